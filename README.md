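# hitchsweep

Genetic hitchhiking in a two-locus, two-allele system with **recurrent
beneficial mutation** and **purifying selection at the linked locus** — a
library and CLI for population geneticists studying selective sweeps and the
conditions under which multiple-origin soft sweeps arise.

The classical hitchhiking model (Maynard Smith–Haigh) follows a single
beneficial allele *B* sweeping past a neutral linked polymorphism *A*/*a*.
`hitchsweep` extends it in two directions:

1. *B* keeps arising by mutation at rate μ_B, so beneficial copies can
   originate on both the *A* and the *a* background. The ratio
   **κ = μ_B/s₂** (mutation rate over selection coefficient) separates
   mutation-dominated from selection-dominated growth of *B* and governs how
   often a sweep ends with both origin backgrounds common — a
   multiple-origin soft sweep.
2. The linked polymorphism may be *deleterious*, maintained in
   mutation–selection balance at frequency p₂₀ = μ_A/|s₁|. The post-sweep
   heterozygosity ratio is then

   H(τ̂)/H(0) ≈ (1 − X) + (r/(μ_A + r))·X·(1 − Y),
   X = x₀^(−2s₁/s₂), Y = x₀^(2(μ_A+r)/s₂),

   which is strictly larger than the neutral value (1 − x₀^(2r/s₂)): a sweep
   removes less relative variation from a balanced polymorphism than from a
   neutral one, because mutation keeps reseeding the deleterious allele on
   the sweeping background.

The package provides:

- the exact gamete-frequency ODEs and their haplotype-structure form
  (x, p₁, p₂), with coordinate changes and observables (D, p_A, H);
- adaptive ODE integration of the deterministic sweep phase plus the exact
  and approximate closed-form solutions of the three analytic regimes;
- diffusion moments of the stochastic initial phase (m₁, variance, the
  σ(t) decay law, the threshold time t̄₀ = (1/α)·ln(1 + 2αx₀/θ)) and the
  semi-deterministic pipeline that stitches both phases;
- a seeded two-locus Wright–Fisher forward simulator with hard/soft sweep
  classification and κ-scans;
- a `hitchsweep` CLI writing reproducible JSON summaries and TSV tables.

## Worked example

How much linked variation survives a sweep (s₂ = 0.01, x₀ = 0.005) when the
linked allele is deleterious (s₁ = −0.001, μ_A = 10⁻⁵, so p₂₀ = 0.01) and
completely linked (r = 0)?

```sh
hitchsweep het-ratio --s1 -0.001 --s2 0.01 --mu-a 1e-5 --r 0 --x0 0.005
```

```json
{
  "H_ratio_closed_form": 0.6534275784224268,
  "H_ratio_numeric": 0.6592806053044389,
  "p_end_closed_form": 0.006534275784224268,
  "p_end_numeric": 0.006537307990414046,
  "relative_disagreement": 0.008877899387483543,
  "tau_hat": 1059.6634733096073
}
```

The sweep lasts τ̂ ≈ 1060 generations, after which about **65%** of the
heterozygosity at the linked locus survives (closed form
1 − 0.005^0.2 = 0.6534; full ODE integration 0.6593). A *neutral*
polymorphism at r = 0 would be wiped out entirely (ratio ≈ 0) — purifying
selection weakens the hitchhiking effect.

How does the soft-sweep fraction respond to κ = μ_B/s₂?

```sh
hitchsweep scan --n 2000 --s2 0.05 --kappa 5e-5,5e-4,5e-3 --reps 100 --seed 1
```

reports `prop_soft_by_kappa: [0.04, 0.24, 0.84]` — at N = 2000 the fraction
of completed sweeps carrying beneficial copies from both backgrounds above
5% rises from 4% to 84% as κ grows hundredfold, the signature of
multiple-origin soft sweeps under increasing mutational supply.

Other subcommands: `integrate` (general ODE runs), `sweep` (the
semi-deterministic pipeline, diffusion handover or Wright–Fisher-sampled
handover), `moments` (initial-phase moment tables), `simulate`
(Wright–Fisher replicates with classification). All accept a YAML config
file via `--config`; every seeded run is byte-reproducible.

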