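# Methods

## The model

`hitchsweep` implements a deterministic–stochastic treatment of genetic
hitchhiking in a diploid, two-locus, two-allele system with additive fitness.
A strongly beneficial allele **B** (selection coefficient `s2 > 0`) arises by
recurrent mutation (rate `mu_B` per gamete per generation, back-mutation
fixed at zero) and sweeps to fixation. A linked locus segregates **A**/**a**
with selection coefficient `s1` (`|s1| << s2`; `s1 < 0` means A is
deleterious), two-way mutation (`mu_A`, `mu_Abar`) and recombination fraction
`r` to the selected locus.

In gamete coordinates `(x1, x2, x3, x4)` — frequencies of AB, aB, Ab, ab —
each gamete changes by its additive fitness excess over the population mean,
by mutational exchange, and by recombination acting through linkage
disequilibrium `D = x1 x4 − x2 x3`. The frequency `x4` is never integrated
independently; it is defined by conservation, so the simplex constraint is
exact. The equivalent haplotype-structure coordinates are `x = x1 + x2`
(frequency of B), `p1 = x1/x` (frequency of A among B gametes) and
`p2 = x3/(1−x)`; there `D = x(1−x)(p1 − p2)` and

    dx/dt = ([s1 (p1 − p2) + s2] x + mu_B)(1 − x).

The two right-hand sides are tied together by an exact chain-rule identity,
which the test suite uses as its central oracle: over random states and
parameters the pushforward of the gamete rates matches the transformed rates
to better than 1e-10. The `(p1, p2)` chart is singular at `x ∈ {0, 1}`;
transformed-coordinate operations reject `x` within 1e-12 of the boundary.

## Deterministic phase: closed forms and their regimes

The deterministic description is valid once `x` exceeds a threshold `x0`,
conventionally `5/alpha` with `alpha = 2 N s2`. Three regimes admit closed
forms; each refuses parameters outside its regime rather than extrapolating,
and the general model always remains available through adaptive integration
(`integrate_sweep`: DOP853 at rtol 1e-10/atol 1e-12 with event detection on
`x = stop_at_x`, LSODA fallback on integrator failure — stiffness is not
expected since all per-generation rates are far below 1).

**Recurrent beneficial mutation, complete linkage** (`mu_B > 0`, `r = 0`,
neutral A): separation of variables gives the exact solution
`p1 − p2 = C (s2 x + mu_B)/x` with `C = x0/(s2 x0 + mu_B)(p10 − p20)`, `p2`
constant, and `x(t)` in closed form. The quantity `kappa = mu_B/s2` separates
mutation-dominated growth (`x < kappa`) from selection-dominated growth; a
larger `kappa` leaves more room for beneficial copies on both backgrounds to
rise together, i.e. for multiple-origin soft sweeps.

**Mutation plus recombination** (`r >= 0`): the same structure with exponent
`rho = r/(s2 + mu_B)`:
`p1 − p2 = C~ (1−x)^rho (s2 x + mu_B)^(1−rho)/x`. This expression solves its
ODE exactly (verified to 1e-8 against integration); the companion `p2`
expression is first order in `rho` and is implemented with its integration
constant retained, so `p2(x0) = p20` holds exactly and the constant-free
form is recovered as `x0 → 0`. A warning is emitted for `rho > 0.1`.

**Mutation–selection balance at the linked locus** (`mu_B = 0`, `s1 < 0`,
`mu_A > 0`): A sits at equilibrium frequency `p20 = mu_A/|s1|` (reverse
mutation neglected, `p20 < 0.1` assumed; larger values warn). With the
beneficial mutation arising on the a background (`p10 = 0`), linearizing in
the small quantities `p1, p2` around the logistic sweep gives

    p1(tau) = p20 (1 − X) + p20 (r/(mu_A + r)) X (1 − Y),
    X = e^{s1 tau},  Y = e^{−(mu_A + r) tau},

and at the end of the selective phase `tau_hat = −(2/s2) ln x0` the
heterozygosity ratio `H(tau_hat)/H(0)` equals the same bracket. In the
neutral limit this reduces to the classical `1 − x0^{2r/s2}`; with purifying
selection the ratio at `r = 0` is `1 − x0^{−2 s1/s2} > 0`: the sweep removes
*less* relative variation than it would from a neutral polymorphism, because
mutation–selection balance keeps regenerating the deleterious allele on the
sweeping background during the sweep. Both a closed-form and a numeric mode
are provided; the numeric mode (full ODE integration plus `H = 2p(1−p)`)
is authoritative whenever the two disagree.

**Approximation control for the balance regime.** The closed form treats the
recombination influx integral `∫ (1−x(u)) e^{−(mu_A+r)u} du` as if
`1 − x(u) ≈ 1` throughout the sweep. By logistic symmetry `1 − x(u)` drops to
one half of the sweep duration's worth of area, so when
`(mu_A + r) tau_hat << 1` the closed form overestimates this term by a factor
approaching 2. Consequently the closed-vs-numeric relative error in
`p1(tau_hat)` grows as `|s1| tau_hat` shrinks (the recombination term then
dominates) and can exceed 15% for, e.g., `s2 = 0.05`, `s1 = −0.001`,
`r = 5e-4`; it shrinks again as `r → 0` at fixed `s1` (0.2% at `r = 0`).
For the slower sweeps where the heterozygosity ratio is typically evaluated
(`s2 = 0.01`, `|s1| tau_hat ≈ 1`) the two modes agree within 10%. The
numeric mode should be preferred for quantitative work; the closed form is
kept for its interpretability and limits.

`tau_hat` defaults to the printed `−(2/s2) ln x0`; the exact logistic transit
`(2/s2) ln((1−x0)/x0)` is available via `exact=True` (they differ at O(x0)).

## Stochastic initial phase: diffusion moments

Below `x0` the beneficial allele is governed by drift, selection and
mutational influx. On the diffusion scale (time in units of 2N generations,
`alpha = 2 N s2`, `theta = 4 N mu_B`) the drift coefficient is
`alpha z + theta/2` and the diffusion coefficient `z` — both linear — so the
first two moments close exactly:

    m1(t) = (theta/2 alpha)(e^{alpha t} − 1),   var(t) = m1(t)^2 / theta.

No attempt is made to solve the forward equation for the full density; the
Wright–Fisher simulator supplies distributional checks instead. The Ab
gamete decays as `sigma(t) = x3* exp(−m1(t))` (with `x3*` the frequency of A
at the onset of selection), and inside the window `t <= 2 t0bar` the AB
moments are `m1^{(x1)} = x3* m1` and
`var^{(x1)} = (m1^{(x1)})^2/(theta x3*)`; beyond the window a warning is
attached. The mean
trajectory reaches `x0` at

    t0bar = (1/alpha) ln(1 + 2 alpha x0 / theta),

whose inversion identity `m1(t0bar) = x0` holds to machine precision. The
handover to the deterministic phase sets `p10 = p20 = x3*` and
`t0 = 2N t0bar` (the single place where diffusion time is converted to
generations); equal backgrounds make the Case-1 constant vanish, so `x1/x`
stays constant through the deterministic phase — mutation competes with
selection only during the initial phase. The moment prediction of `p10`
carries a large coefficient of variation `sqrt(1/(theta x3*))` (≈7.5 at
`theta = 0.02`), which `deterministic_init` reports alongside the handover;
the `sampled_init` mode of `semideterministic_sweep` instead draws the
handover state from the Wright–Fisher engine at the first generation with
`x >= x0` (no sub-generation interpolation; the overshoot is kept).

**What t0bar is and is not.** `t0bar` inverts the *unconditional ensemble
mean*. For realistic small `theta` the frequency distribution at fixed time
is extremely skewed (CV `= 1/sqrt(theta)`): the mean is carried by rare
replicates whose first beneficial copy established almost immediately, while
a typical replicate waits on the order of `1/(2N mu_B · 2 s2)` generations
for its first establishing origin. The mean *first-hitting* time of `x0` in
a finite population is therefore many times `2N t0bar` (measured: ≈8–9× at
`alpha = 500`, `theta = 0.02`). Likewise, at `t0bar` itself the upper tail
of the distribution has already left the linear regime (`x ~ 0.3–0.7`), so
the Wright–Fisher ensemble mean and variance fall short of the linear-
diffusion moments there — two discretization/saturation effects compound:
the logistic `(1−x)` factor the linear drift drops, and per-generation
compounding `(1+s2)^t` versus the diffusion's `e^{s2 t}` (a 16% deficit on
tail trajectories at `s2 = 0.05` over 124 generations). At `t0bar/2`, where
the whole distribution is still small, the agreement is within Monte-Carlo
error. The test suite asserts both comparisons separately so the domain of
validity is visible.

## Wright–Fisher engine and soft-sweep classification

The simulator is the synthetic-data engine and brute-force oracle. Each
generation applies one Euler step of the full deterministic right-hand side
(selection, mutation, recombination jointly — correct to first order because
every rate is at most ~0.05 per generation) and then resamples `2N` gametes
multinomially; frequencies therefore remain exactly on the simplex, and a
parameter set whose expected update leaves the simplex by more than 1e-6
raises an error rather than being clipped silently. Passing no RNG returns
the expectation itself, giving an infinite-population surrogate that tracks
the ODEs to O(rates²) per generation. The engine is validated independently
of the sweep model by the classical neutral checks (single-generation
binomial sampling variance; heterozygosity decay by `1 − 1/(2N)` per
generation).

A replicate runs from `x = 0` (B absent, A at `x3*`) until the first
generation with `x >= 1 − x0` — the end of the selective phase, chosen over
absolute fixation to match `tau_hat` and avoid long neutral tails — or a
generation cap. It is a **multiple-origin soft sweep** if both `x1 > eps`
and `x2 > eps` at that moment (detection threshold `eps = 0.05` by default,
configurable), i.e. beneficial copies descending from origins on both
backgrounds are simultaneously common; otherwise **hard**. With the two
backgrounds A/a there are exactly two origin classes, so no further
infinite-alleles bookkeeping is needed.

All randomness flows from a single integer seed through
`numpy.random.SeedSequence([seed, replicate_index, ...])` substreams
(PCG64), making every output — including CLI files — reproducible byte for
byte.

**Scans.** `softness_scan` varies `kappa = mu_B/s2` through `mu_B` at fixed
`s2` (so `theta` co-varies with `kappa`); the soft proportion among
completed sweeps rises steeply with `kappa` (at `N = 2000`, `s2 = 0.05`,
500 replicates: 0.02 → 0.21 → 0.86 over `kappa = 5e-5, 5e-4, 5e-3`).
`selection_scan` varies `s2` at fixed `mu_B` — the complementary axis. There
the measured soft proportion is *not* decreasing in `s2` despite the falling
`kappa`: with `theta` fixed, softness is governed by the scaled mutation
rate, and faster sweeps lose fewer minor-background copies to drift before
classification (3000-replicate check: 0.823 → 0.851 → 0.871 for
`s2 = 0.02, 0.05, 0.1` at `theta = 2`). A strong negative selection effect
is expected only under a fixed-time detection horizon (as in HIV-style
simulation protocols), which this endpoint-based classification
deliberately does not impose. Both axes are reported so the two effects can
be distinguished.

## Numerical choices and problem sizes

- ODE integration: DOP853, rtol 1e-10, atol 1e-12, event detection for the
  stop frequency, generous time cap (~10× the logistic transit) with an
  explicit "sweep did not complete" error carrying the partial trajectory.
- Boundary guards: `x` within 1e-12 of 0 or 1 is rejected in the transformed
  chart; simplex tolerance 1e-9 on gamete frequencies.
- Default `x0 = 5/alpha` wherever a population size is known; overridable.
- Trajectories are plain TSV (10 significant digits) with a fixed column
  order; summaries are sorted-key JSON, so reruns diff cleanly.
- Study sizes used by the test suite and the acceptance script: 1000 random
  draws for the coordinate oracle; 20 parameter draws for the Case-1 oracle;
  2000 (tests) or 800 (script) Wright–Fisher replicates at `N = 5000` for
  the diffusion comparison; 500 (tests) or 300 (script) replicates per scan
  point at `N = 2000`. At these sizes the whole suite runs in well under a
  minute on one core.

## Known limitations

- The closed forms are regime-gated approximations; outside their stated
  regimes only `integrate_sweep` answers. The balance-regime closed form
  overestimates the recombination influx for `(mu_A + r) tau_hat << 1` (see
  approximation control above).
- The diffusion moments describe the unconditional ensemble; they are not
  first-passage quantities, and their accuracy at `t0bar` is limited by
  logistic saturation of the heavy upper tail.
- The simulator's one-Euler-step life cycle is first-order in the rates;
  per-generation compounding deviates from continuous time by
  O(s2²) per generation, visible over hundreds of generations at `s2 ≳ 0.05`.
- Constant population size, additive fitness, two alleles per locus; no
  demography, dominance, interference between sweeps, or coalescent
  signatures.
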