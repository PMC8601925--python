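"""Diffusion treatment of the stochastic initial phase of a sweep.

Immediately after the onset of selection the beneficial allele B is too rare
for deterministic dynamics: drift, recurrent mutation (influx theta/2 on the
diffusion scale) and selection (alpha z) compete. Rather than solving the
Kolmogorov forward equation, this module tracks the first two moments of the
frequency of B (process ``x``) and of the AB gamete (process ``x1``), which
close exactly because drift and diffusion coefficients are linear in the
state. Time is in units of 2N generations throughout.

Key results implemented here:

* m1(t) = (theta/2 alpha)(e^{alpha t} - 1) and var(t) = m1(t)^2/theta for x;
* the decay law sigma(t) = x3* exp(-m1(t)) of the Ab gamete that feeds the AB
  influx, and the resulting x1 moments m1^{(x1)} = x3* m1,
  var^{(x1)} = m1^2 x3*/... (see :func:`moments_x1_closed`);
* the mean time t0bar = (1/alpha) ln(1 + 2 alpha x0/theta) at which the mean
  trajectory reaches the deterministic threshold x0;
* the handover p10 ~ p20 ~ x3* that initializes the deterministic phase, so
  the subsequent sweep has constant x1/x (Case-1 constant C = 0).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .model import (
    DiffusionScale,
    ModelAssumptionWarning,
    SweepParams,
    TIME_SCALE_GENERATIONS,
    Trajectory,
)
from .deterministic import (
    InitialConditions,
    SweepIncompleteError,
    SweepSummary,
    integrate_sweep,
)

__all__ = [
    "DiffusionSpec",
    "MomentState",
    "SemiDeterministicInit",
    "moment_rhs",
    "moments_x_closed",
    "sigma_decay",
    "moments_x1_closed",
    "mean_time_to_threshold",
    "deterministic_init",
    "semideterministic_sweep",
]


@dataclass(frozen=True)
class DiffusionSpec:
    """Scaled parameters of the initial-phase diffusion.

    ``x3_star`` is the frequency of allele A at the onset of selection; new B
    copies arise on the A background in proportion sigma(t)/x3_star.
    The approximations used here are tailored to the biologically relevant
    range alpha > 100, theta > 0.005; outside it a warning is emitted and
    :attr:`in_valid_range` is False.
    """

    scale: DiffusionScale
    x3_star: float

    def __post_init__(self) -> None:
        if not 0.0 < self.x3_star < 1.0:
            raise ValueError(f"x3_star = {self.x3_star} must lie in (0, 1)")
        if not self.in_valid_range:
            warnings.warn(
                f"alpha = {self.scale.alpha}, theta = {self.scale.theta} outside the "
                "biologically relevant range (alpha > 100, theta > 0.005)",
                ModelAssumptionWarning,
                stacklevel=2,
            )

    @property
    def in_valid_range(self) -> bool:
        return self.scale.alpha > 100.0 and self.scale.theta > 0.005


@dataclass(frozen=True)
class MomentState:
    """First and second moment of a frequency process; var = m2 - m1^2."""

    m1: float
    m2: float

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.m1) < -1e-12):
            raise ValueError(f"m1 = {self.m1} must be >= 0")
        if np.any(np.asarray(self.m2) - np.asarray(self.m1) ** 2 < -1e-6):
            raise ValueError("m2 < m1^2: negative variance")

    @property
    def var(self):
        return self.m2 - np.asarray(self.m1) ** 2


def moment_rhs(
    state: MomentState, spec: DiffusionSpec, which: str = "x", t: float = 0.0
) -> tuple[float, float]:
    """Moment ODE right-hand side (dm1/dt, dm2/dt) on the 2N time scale.

    For the B-frequency process: dm1 = theta/2 + alpha m1,
    dm2 = (1 + theta) m1 + 2 alpha m2. For the AB-gamete process the mutational
    influx is modulated by sigma(t), the decaying frequency of Ab gametes.
    """
    alpha, theta = spec.scale.alpha, spec.scale.theta
    if which == "x":
        influx = theta / 2.0
        m2_mut = theta
    elif which == "x1":
        s = sigma_decay(t, spec)
        influx = theta / 2.0 * s
        m2_mut = theta * s
    else:
        raise ValueError(f"which must be 'x' or 'x1', got {which!r}")
    dm1 = influx + alpha * state.m1
    dm2 = (1.0 + m2_mut) * state.m1 + 2.0 * alpha * state.m2
    return dm1, dm2


def moments_x_closed(t, spec: DiffusionSpec) -> MomentState:
    """Closed-form moments of the B-frequency process started at x = 0.

    m1 = (theta/2 alpha)(e^{alpha t} - 1), m2 = (1 + 1/theta) m1^2; hence
    var = m1^2/theta, i.e. a coefficient of variation 1/sqrt(theta) that is
    large for realistic (small) scaled mutation rates.
    """
    t = np.asarray(t, dtype=float)
    alpha, theta = spec.scale.alpha, spec.scale.theta
    m1 = theta / (2.0 * alpha) * np.expm1(alpha * t)
    m2 = (1.0 + 1.0 / theta) * m1**2 if theta > 0 else np.zeros_like(m1)
    if t.ndim == 0:
        return MomentState(m1=float(m1), m2=float(m2))
    return MomentState(m1=m1, m2=m2)


def sigma_decay(t, spec: DiffusionSpec) -> float | np.ndarray:
    """Frequency of the Ab gamete during the initial phase.

    Ab is depleted by mutation to AB and by the rise of B:
    sigma(t) = x3* exp(-(theta/2 alpha)(e^{alpha t} - 1)) = x3* exp(-m1(t)).
    """
    t = np.asarray(t, dtype=float)
    alpha, theta = spec.scale.alpha, spec.scale.theta
    out = spec.x3_star * np.exp(-theta / (2.0 * alpha) * np.expm1(alpha * t))
    return float(out) if t.ndim == 0 else out


def moments_x1_closed(t, spec: DiffusionSpec, *, x0: float | None = None) -> MomentState:
    """Closed-form moments of the AB-gamete frequency process.

    m1 = x3* (theta/2 alpha)(e^{alpha t} - 1) and
    m2 = (1 + 1/(theta x3*)) m1^2. Valid for t up to about twice the threshold
    time t0bar (beyond that the sigma(t) decay invalidates the approximation);
    a warning is attached when evaluated beyond the window. ``x0`` (default
    5/alpha) only enters the validity-window check.
    """
    t = np.asarray(t, dtype=float)
    alpha, theta = spec.scale.alpha, spec.scale.theta
    if x0 is None:
        x0 = 5.0 / alpha
    window = 2.0 * mean_time_to_threshold(spec, x0)
    if np.any(t > window):
        warnings.warn(
            f"t beyond the validity window 2*t0bar = {window:.4g} (2N units) of the "
            "x1 moment approximation",
            ModelAssumptionWarning,
            stacklevel=2,
        )
    m1 = spec.x3_star * theta / (2.0 * alpha) * np.expm1(alpha * t)
    m2 = (1.0 + 1.0 / (theta * spec.x3_star)) * m1**2 if theta > 0 else np.zeros_like(m1)
    if t.ndim == 0:
        return MomentState(m1=float(m1), m2=float(m2))
    return MomentState(m1=m1, m2=m2)


def mean_time_to_threshold(spec: DiffusionSpec, x0: float) -> float:
    """Time t0bar (2N units) at which the mean trajectory m1(t) reaches x0.

    t0bar = (1/alpha) ln(1 + 2 alpha x0/theta), the exact inverse of the
    closed-form m1. Note this is the crossing time of the ensemble mean, not
    the mean first-hitting time of a finite-population process; for small
    theta the two differ substantially (the mean is carried by rare,
    early-establishing replicates).
    """
    if not 0.0 < x0 < 1.0:
        raise ValueError(f"x0 = {x0} must lie in (0, 1)")
    alpha, theta = spec.scale.alpha, spec.scale.theta
    if theta <= 0:
        raise ValueError("mean_time_to_threshold requires theta > 0")
    return math.log1p(2.0 * alpha * x0 / theta) / alpha


@dataclass(frozen=True)
class SemiDeterministicInit:
    """Deterministic-phase initial conditions derived from the diffusion.

    ``init.t0`` is 2N * t0bar in generations. ``cv_p10`` is the predicted
    coefficient of variation sqrt(1/(theta x3*)) of x1 at the handover: the
    moment prediction p10 = x3* carries large relative uncertainty.
    """

    init: InitialConditions
    t0bar: float
    cv_p10: float


def deterministic_init(spec: DiffusionSpec, x0: float) -> SemiDeterministicInit:
    """Initial conditions for the deterministic phase at x = x0.

    The moment analysis gives p1(t0) = m1^{(x1)}/m1^{(x)} = x3* and
    p2(t0) = sigma(t0)/(1 - x0) which is also close to x3*; both backgrounds
    therefore carry A at its pre-sweep frequency, the Case-1 constant C
    vanishes, and x1/x stays constant through the deterministic phase.
    """
    t0bar = mean_time_to_threshold(spec, x0)
    theta = spec.scale.theta
    cv = math.sqrt(1.0 / (theta * spec.x3_star)) if theta > 0 else math.inf
    init = InitialConditions(
        x0=x0, p10=spec.x3_star, p20=spec.x3_star, t0=2.0 * spec.scale.N * t0bar
    )
    return SemiDeterministicInit(init=init, t0bar=t0bar, cv_p10=cv)


def _check_consistency(params: SweepParams, spec: DiffusionSpec) -> None:
    N = spec.scale.N
    if not math.isclose(spec.scale.alpha, 2.0 * N * params.s2, rel_tol=1e-9):
        raise ValueError(
            f"alpha = {spec.scale.alpha} inconsistent with 2*N*s2 = {2 * N * params.s2}"
        )
    if not math.isclose(spec.scale.theta, 4.0 * N * params.mu_B, rel_tol=1e-9, abs_tol=1e-15):
        raise ValueError(
            f"theta = {spec.scale.theta} inconsistent with 4*N*mu_B = {4 * N * params.mu_B}"
        )


def semideterministic_sweep(
    params: SweepParams,
    spec: DiffusionSpec,
    x0: float | None = None,
    mode: str = "moment_init",
    seed: int | None = None,
    *,
    stop_at_x: float | None = None,
    record_every: int = 1,
    max_generations: int = 2_000_000,
    **integrate_kw,
) -> tuple[Trajectory, SweepSummary]:
    """Full sweep: stochastic initial phase stitched to the deterministic phase.

    ``moment_init`` initializes the deterministic ODEs from the diffusion
    moments (p10 = p20 = x3*, t0 = 2N t0bar) and prepends the mean-moment path
    of the initial phase; ``sampled_init`` instead runs the Wright-Fisher
    simulator (mandatory ``seed``) until the first generation with x >= x0 and
    hands that sampled state — overshoot included — to the ODEs. The returned
    trajectory is in generations with the phase boundary marked.
    """
    _check_consistency(params, spec)
    alpha = spec.scale.alpha
    if x0 is None:
        x0 = 5.0 / alpha
    if stop_at_x is None:
        stop_at_x = 1.0 - x0
    kappa = params.mu_B / params.s2

    if mode == "moment_init":
        sd = deterministic_init(spec, x0)
        det = integrate_sweep(params, sd.init, stop_at_x, **integrate_kw)
        # Mean-moment path of the initial phase, in gamete coordinates
        # (the haplotype chart is singular at x = 0).
        N2 = 2.0 * spec.scale.N
        t_init = np.linspace(0.0, sd.init.t0, 101)[:-1]
        m1 = moments_x_closed(t_init / N2, spec).m1
        xs = np.clip(np.asarray(m1), 0.0, 1.0)
        g = np.column_stack(
            [
                spec.x3_star * xs,
                (1.0 - spec.x3_star) * xs,
                np.asarray(sigma_decay(t_init / N2, spec)),
                np.zeros_like(xs),
            ]
        )
        g[:, 3] = 1.0 - g[:, 0] - g[:, 1] - g[:, 2]
        initial = Trajectory.from_gametes(t_init, g, TIME_SCALE_GENERATIONS)
        traj = initial.concat(det)
        traj.phase_boundary = sd.init.t0
        t0 = sd.init.t0
    elif mode == "sampled_init":
        if seed is None:
            raise ValueError("sampled_init mode requires a seed")
        from .wright_fisher import GameteFreqs, SimConfig, _evolve_until

        g0 = GameteFreqs(0.0, 0.0, spec.x3_star, 1.0 - spec.x3_star)
        cfg = SimConfig(
            params=params, N=spec.scale.N, init=g0, seed=seed,
            max_generations=max_generations, record_every=record_every, x0=x0,
        )
        rec_t, rec_g, hit_gen, _, hit_state = _evolve_until(cfg, target_x=x0)
        if hit_gen is None:
            raise SweepIncompleteError(
                f"threshold x0 = {x0} not reached within {max_generations} generations",
                Trajectory.from_gametes(np.asarray(rec_t, float), np.asarray(rec_g)),
            )
        x1, x2, x3, x4 = hit_state
        x_hit = x1 + x2
        init = InitialConditions(
            x0=x_hit, p10=x1 / x_hit, p20=x3 / (1.0 - x_hit), t0=float(hit_gen)
        )
        det = integrate_sweep(params, init, stop_at_x, **integrate_kw)
        wf_part = Trajectory.from_gametes(np.asarray(rec_t, float), np.asarray(rec_g))
        traj = wf_part.concat(det)
        traj.phase_boundary = float(hit_gen)
        t0 = float(hit_gen)
    else:
        raise ValueError(f"mode must be 'moment_init' or 'sampled_init', got {mode!r}")

    end = traj.frame.iloc[-1]
    # Heterozygosity surviving the deterministic phase, relative to the handover.
    idx0 = int(np.searchsorted(traj.times, t0))
    H0 = float(traj.frame["H"].iloc[min(idx0, len(traj) - 1)])
    H_ratio = float(end["H"]) / H0 if H0 > 0 else 1.0
    summary = SweepSummary(
        tau_hat=float(end["time"]) - t0,
        p_end=float(end["p_A"]),
        H_ratio=min(max(H_ratio, 0.0), 1.0),
        kappa=kappa,
        x0=x0,
        mode=mode,
        final_state=None,
    )
    return traj, summary
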