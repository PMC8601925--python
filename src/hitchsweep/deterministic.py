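"""Deterministic phase of the sweep: numerical integration and closed forms.

Once the beneficial allele B has escaped drift (frequency above the
deterministic threshold x0, conventionally 5/alpha), its trajectory and the
haplotype structure at the linked locus follow the ODEs of
:mod:`hitchsweep.model`. Three parameter regimes admit closed-form solutions:

* **Case 1** — recurrent beneficial mutation, no recombination, neutral linked
  locus: p1 - p2 decays as C (s2 x + mu_B)/x along the sweep, and the soft-sweep
  threshold parameter kappa = mu_B/s2 separates mutation-dominated (x < kappa)
  from selection-dominated (x > kappa) growth.
* **Case 2** — mutation plus recombination: the same structure with exponent
  rho = r/(s2 + mu_B); the p1 - p2 expression is exact, the p2 expression is a
  small-rho approximation.
* **Case 3** — no beneficial mutation, deleterious A maintained in
  mutation-selection balance at frequency mu_A/|s1|: the classical hitchhiking
  scenario with purifying instead of neutral variation at the linked site. The
  headline result is that the relative reduction of heterozygosity after the
  sweep is smaller than for a neutral polymorphism.

Closed forms refuse parameters outside their stated regime; general parameter
sets go through :func:`integrate_sweep`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy.integrate import solve_ivp

from .model import (
    DomainError,
    GameteFreqs,
    HaploState,
    ModelAssumptionWarning,
    SweepParams,
    Trajectory,
    UnsupportedRegimeError,
    _haplo_rhs_raw,
    to_gametes,
)

__all__ = [
    "InitialConditions",
    "Case1Constants",
    "Case2Constants",
    "SweepSummary",
    "SweepIncompleteError",
    "integrate_sweep",
    "case1_solution",
    "case1_x_of_t",
    "case2_solution",
    "case3_solution",
    "sweep_duration",
    "het_ratio_after_sweep",
    "soft_sweep_threshold",
]


@dataclass(frozen=True)
class InitialConditions:
    """State of (x, p1, p2) at the start of the deterministic phase.

    ``t0`` is the time offset (generations) at which the deterministic phase
    begins, i.e. the duration of the stochastic initial phase.
    """

    x0: float
    p10: float
    p20: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.x0 < 1.0:
            raise DomainError(f"x0 = {self.x0} must lie in (0, 1)")
        for name in ("p10", "p20"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} = {v} must lie in [0, 1]")


@dataclass(frozen=True)
class Case1Constants:
    """Integration constant C = x0/(s2 x0 + mu_B) * (p10 - p20)."""

    C: float

    @classmethod
    def from_conditions(cls, params: SweepParams, init: InitialConditions) -> "Case1Constants":
        C = init.x0 / (params.s2 * init.x0 + params.mu_B) * (init.p10 - init.p20)
        return cls(C=C)


@dataclass(frozen=True)
class Case2Constants:
    """rho = r/(s2 + mu_B) and the Case-2 integration constant C_tilde."""

    rho: float
    C_tilde: float

    @classmethod
    def from_conditions(cls, params: SweepParams, init: InitialConditions) -> "Case2Constants":
        rho = params.r / (params.s2 + params.mu_B)
        if rho > 0.1:
            warnings.warn(
                f"rho = r/(s2 + mu_B) = {rho:.4g} > 0.1; the Case-2 p2 "
                "approximation assumes rho << 1",
                ModelAssumptionWarning,
                stacklevel=2,
            )
        C_tilde = (
            init.x0
            * (1.0 - init.x0) ** (-rho)
            * (params.s2 * init.x0 + params.mu_B) ** (rho - 1.0)
            * (init.p10 - init.p20)
        )
        return cls(rho=rho, C_tilde=C_tilde)


@dataclass(frozen=True)
class SweepSummary:
    """Headline numbers of a completed sweep at the linked locus."""

    tau_hat: float
    p_end: float
    H_ratio: float
    kappa: float
    x0: float
    mode: str
    final_state: GameteFreqs | None = None

    def __post_init__(self) -> None:
        if self.tau_hat <= 0:
            raise ValueError(f"tau_hat must be positive, got {self.tau_hat}")
        # Mutational input over a long sweep can push H(tau_hat) marginally
        # above H(0), so the upper bound is soft.
        if not -1e-9 <= self.H_ratio <= 1.0 + 1e-2:
            raise ValueError(f"H_ratio = {self.H_ratio} outside [0, 1]")


class SweepIncompleteError(RuntimeError):
    """The integration cap was reached before x hit the stop frequency."""

    def __init__(self, message: str, trajectory: Trajectory):
        super().__init__(message)
        self.trajectory = trajectory


class Case1Solution(NamedTuple):
    p1_minus_p2: np.ndarray
    p1: np.ndarray
    p2: np.ndarray
    x1: np.ndarray
    x2: np.ndarray


class Case2Solution(NamedTuple):
    p1_minus_p2: np.ndarray
    p2_approx: np.ndarray


class Case3Solution(NamedTuple):
    x: np.ndarray
    p1_minus_p2: np.ndarray
    p1: np.ndarray
    p2: np.ndarray


def _check_regime(name: str, conditions: dict[str, bool]) -> None:
    violated = [desc for desc, ok in conditions.items() if not ok]
    if violated:
        raise UnsupportedRegimeError(
            f"{name} closed form requires: " + "; ".join(violated)
        )


def _require_case1(params: SweepParams) -> None:
    _check_regime(
        "Case 1",
        {
            "s2 > 0": params.s2 > 0,
            "mu_B > 0": params.mu_B > 0,
            "r = 0": params.r == 0,
            "mu_A = 0": params.mu_A == 0,
            "mu_Abar = 0": params.mu_Abar == 0,
            "s1 = 0": params.s1 == 0,
        },
    )


def _require_case2(params: SweepParams) -> None:
    _check_regime(
        "Case 2",
        {
            "s2 > 0": params.s2 > 0,
            "mu_B > 0": params.mu_B > 0,
            "r >= 0": params.r >= 0,
            "mu_A = 0": params.mu_A == 0,
            "mu_Abar = 0": params.mu_Abar == 0,
            "s1 = 0": params.s1 == 0,
        },
    )


def _require_case3(params: SweepParams, allow_neutral: bool = False) -> None:
    s1_ok = params.s1 < 0 or (allow_neutral and params.s1 == 0)
    mu_ok = params.mu_A > 0 or (allow_neutral and params.s1 == 0)
    _check_regime(
        "Case 3",
        {
            "s2 > 0": params.s2 > 0,
            "mu_B = 0": params.mu_B == 0,
            "mu_Abar = 0": params.mu_Abar == 0,
            "s1 < 0 (deleterious A)": s1_ok,
            "mu_A > 0": mu_ok,
        },
    )


def mutation_selection_balance(params: SweepParams) -> float:
    """Equilibrium frequency mu_A/|s1| of the deleterious allele A (Case 3)."""
    if params.s1 >= 0:
        raise UnsupportedRegimeError(
            "mutation-selection balance requires s1 < 0 (deleterious A)"
        )
    return params.mu_A / abs(params.s1)


def integrate_sweep(
    params: SweepParams,
    init: InitialConditions,
    stop_at_x: float,
    *,
    rtol: float = 1e-10,
    atol: float = 1e-12,
    max_time: float | None = None,
    n_points: int = 400,
    method: str = "DOP853",
) -> Trajectory:
    """Integrate the transformed ODEs from ``init`` until x reaches ``stop_at_x``.

    Uses an adaptive non-stiff Runge-Kutta method with event detection on
    x = stop_at_x, falling back to LSODA if the integrator fails (stiffness is
    not expected since all per-generation rates are << 1). Returns a
    :class:`Trajectory` in generations with derived columns.

    Raises
    ------
    SweepIncompleteError
        If the time cap is hit before the event; carries the partial trajectory.
    """
    if not init.x0 < stop_at_x < 1.0:
        raise DomainError(f"stop_at_x = {stop_at_x} must lie in (x0, 1)")

    pt = params.as_tuple()

    def rhs(t, y):
        x = min(max(y[0], 1e-300), 1.0 - 1e-16)
        return _haplo_rhs_raw(x, y[1], y[2], *pt)

    def reach_stop(t, y):
        return y[0] - stop_at_x

    reach_stop.terminal = True
    reach_stop.direction = 1.0

    if max_time is None:
        # Generous cap: ~10x the logistic transit time from x0 to stop_at_x.
        transit = (
            math.log(stop_at_x / (1.0 - stop_at_x)) - math.log(init.x0 / (1.0 - init.x0))
        ) / params.s2
        max_time = 10.0 * abs(transit) + 100.0

    y0 = [init.x0, init.p10, init.p20]
    t_span = (init.t0, init.t0 + max_time)
    sol = solve_ivp(
        rhs, t_span, y0, method=method, events=reach_stop,
        dense_output=True, rtol=rtol, atol=atol,
    )
    if sol.status < 0 and method != "LSODA":
        sol = solve_ivp(
            rhs, t_span, y0, method="LSODA", events=reach_stop,
            dense_output=True, rtol=rtol, atol=atol,
        )
    if sol.status < 0:
        raise RuntimeError(f"ODE integration failed: {sol.message}")

    if len(sol.t_events[0]) == 0:
        times = np.linspace(t_span[0], sol.t[-1], n_points)
        y = sol.sol(times)
        partial = Trajectory.from_haplo(times, y[0], y[1], y[2])
        raise SweepIncompleteError(
            f"sweep did not complete: x reached only {y[0][-1]:.6g} < {stop_at_x} "
            f"within {max_time:.6g} generations",
            partial,
        )

    t_end = float(sol.t_events[0][0])
    times = np.linspace(init.t0, t_end, n_points)
    y = sol.sol(times)
    x = np.clip(y[0], 0.0, 1.0)
    return Trajectory.from_haplo(times, x, y[1], y[2], phase_boundary=init.t0)


def case1_solution(
    x: float | np.ndarray, params: SweepParams, init: InitialConditions
) -> Case1Solution:
    """Exact haplotype structure as a function of x in the Case-1 regime.

    p1 - p2 = C (s2 x + mu_B)/x with C fixed by the initial conditions; p2 is
    constant (mutation at the selected locus does not touch the b background),
    and x1 = C (s2 x + mu_B) + p20 x, x2 = x - x1.
    """
    _require_case1(params)
    x = np.asarray(x, dtype=float)
    C = Case1Constants.from_conditions(params, init).C
    lin = params.s2 * x + params.mu_B
    diff = C * lin / x
    p2 = np.full_like(x, init.p20)
    p1 = p2 + diff
    x1 = C * lin + init.p20 * x
    return Case1Solution(p1_minus_p2=diff, p1=p1, p2=p2, x1=x1, x2=x - x1)


def case1_x_of_t(
    t: float | np.ndarray, params: SweepParams, x0: float
) -> np.ndarray:
    """Exact solution of dx/dt = (s2 x + mu_B)(1 - x) starting at x0.

    With gamma = s2 + mu_B and K = (s2 x0 + mu_B)/(1 - x0),
    x(t) = (K e^{gamma t} - mu_B)/(s2 + K e^{gamma t}); for mu_B = 0 this is
    the classical logistic sweep of Maynard Smith and Haigh.
    """
    if not 0.0 < x0 < 1.0:
        raise DomainError(f"x0 = {x0} must lie in (0, 1)")
    t = np.asarray(t, dtype=float)
    gamma = params.s2 + params.mu_B
    K = (params.s2 * x0 + params.mu_B) / (1.0 - x0)
    e = K * np.exp(gamma * t)
    return (e - params.mu_B) / (params.s2 + e)


def case2_solution(
    x: float | np.ndarray, params: SweepParams, init: InitialConditions
) -> Case2Solution:
    """Haplotype-frequency difference (exact) and p2 (small-rho) for Case 2.

    p1 - p2 = C_tilde (1-x)^rho (s2 x + mu_B)^{1-rho} / x solves the Case-2
    ODE exactly; p2 is integrated to first order in rho = r/(s2 + mu_B), with
    the integration constant retained so p2(x0) = p20 exactly.
    """
    _require_case2(params)
    x = np.asarray(x, dtype=float)
    consts = Case2Constants.from_conditions(params, init)
    rho, Ct = consts.rho, consts.C_tilde
    diff = Ct * (1.0 - x) ** rho * (params.s2 * x + params.mu_B) ** (1.0 - rho) / x
    p2 = init.p20 - params.r * Ct * (np.log(1.0 - x) - math.log(1.0 - init.x0))
    return Case2Solution(p1_minus_p2=diff, p2_approx=p2)


def case3_solution(
    tau: float | np.ndarray, params: SweepParams, init: InitialConditions
) -> Case3Solution:
    """Approximate closed forms for the mutation-selection-balance sweep.

    Valid for |s1|, r << s2 and small p20; derived by linearizing in p1, p2
    around the logistic trajectory of x. ``tau`` is time since the start of
    the deterministic phase (generations). The initial conditions must have
    p10 = 0 (the beneficial mutation arises on the a background).
    """
    _require_case3(params)
    if init.p10 != 0.0:
        raise UnsupportedRegimeError("Case 3 closed forms assume p10 = 0")
    tau = np.asarray(tau, dtype=float)
    if np.any(tau < 0):
        raise DomainError("tau must be >= 0")
    s1, r, mu_A = params.s1, params.r, params.mu_A
    x0, p20 = init.x0, init.p20
    x = x0 / (x0 + (1.0 - x0) * np.exp(-params.s2 * tau))
    diff = -p20 * np.exp((s1 - mu_A - r) * tau)
    decay = mu_A + r
    if decay > 0:
        p1 = p20 * (1.0 - np.exp(s1 * tau)) + p20 * (r / decay) * np.exp(s1 * tau) * (
            1.0 - np.exp(-decay * tau)
        )
    else:
        p1 = p20 * (1.0 - np.exp(s1 * tau))
    return Case3Solution(x=x, p1_minus_p2=diff, p1=p1, p2=p1 - diff)


def sweep_duration(params: SweepParams, x0: float, *, exact: bool = False) -> float:
    """Duration tau_hat of the deterministic phase (x: x0 -> 1 - x0).

    Default is the logistic-symmetry form -(2/s2) ln(x0); with ``exact=True``
    the exact logistic transit time (2/s2) ln((1-x0)/x0) is returned instead
    (the two agree to O(x0)).
    """
    if params.s2 <= 0:
        raise DomainError("sweep_duration requires s2 > 0")
    if not 0.0 < x0 < 0.5:
        raise DomainError(f"x0 = {x0} must lie in (0, 0.5)")
    if exact:
        return 2.0 / params.s2 * math.log((1.0 - x0) / x0)
    return -2.0 / params.s2 * math.log(x0)


def _closed_form_ratio(params: SweepParams, tau_hat: float) -> float:
    X = math.exp(params.s1 * tau_hat)
    decay = params.mu_A + params.r
    if decay > 0:
        second = (params.r / decay) * X * (1.0 - math.exp(-decay * tau_hat))
    else:
        second = 0.0
    return (1.0 - X) + second


def het_ratio_after_sweep(
    params: SweepParams,
    x0: float,
    mode: str = "closed_form",
    *,
    p20: float | None = None,
    exact_tau: bool = False,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> SweepSummary:
    """Post-sweep reduction of heterozygosity at the linked locus (Case 3).

    Computes H(tau_hat)/H(0), the fraction of heterozygosity surviving the
    sweep. In ``closed_form`` mode the ratio is
    (1 - X) + (r/(mu_A + r)) X (1 - Y) with X = e^{s1 tau_hat} and
    Y = e^{-(mu_A + r) tau_hat}; this reconstruction is exactly the Case-3 p1
    solution evaluated at tau_hat and reduces to 1 - x0^{2r/s2} in the neutral
    limit. In ``numeric`` mode the full transformed ODEs are integrated to
    tau_hat and H = 2p(1-p) evaluated directly; the numeric route is
    authoritative where the two disagree (the closed form is an approximation
    for |s1|, r << s2 and small p20).

    ``p20`` defaults to the mutation-selection balance mu_A/|s1| and must be
    supplied explicitly for a neutral (s1 = 0) linked locus.
    """
    if mode not in ("closed_form", "numeric"):
        raise ValueError(f"mode must be 'closed_form' or 'numeric', got {mode!r}")
    _require_case3(params, allow_neutral=p20 is not None)
    if p20 is None:
        p20 = mutation_selection_balance(params)
    if p20 >= 0.1:
        warnings.warn(
            f"p20 = {p20:.4g} >= 0.1; the heterozygosity-ratio derivation assumes a "
            "small equilibrium frequency of the deleterious allele",
            ModelAssumptionWarning,
            stacklevel=2,
        )
    tau_hat = sweep_duration(params, x0, exact=exact_tau)
    kappa = params.mu_B / params.s2

    if mode == "closed_form":
        ratio = _closed_form_ratio(params, tau_hat)
        p_end = p20 * ratio
        return SweepSummary(
            tau_hat=tau_hat, p_end=p_end, H_ratio=min(max(ratio, 0.0), 1.0),
            kappa=kappa, x0=x0, mode=mode,
        )

    pt = params.as_tuple()

    def rhs(t, y):
        x = min(max(y[0], 1e-300), 1.0 - 1e-16)
        return _haplo_rhs_raw(x, y[1], y[2], *pt)

    sol = solve_ivp(
        rhs, (0.0, tau_hat), [x0, 0.0, p20], method="DOP853",
        rtol=rtol, atol=atol, dense_output=True,
    )
    if sol.status < 0:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    x_end, p1_end, p2_end = sol.y[:, -1]
    p0 = p20 * (1.0 - x0)
    H0 = 2.0 * p0 * (1.0 - p0)
    p_end = p1_end * x_end + p2_end * (1.0 - x_end)
    H_end = 2.0 * p_end * (1.0 - p_end)
    h = HaploState(x=min(max(x_end, 1e-12), 1 - 1e-12), p1=min(max(p1_end, 0.0), 1.0),
                   p2=min(max(p2_end, 0.0), 1.0))
    return SweepSummary(
        tau_hat=tau_hat, p_end=p_end, H_ratio=H_end / H0, kappa=kappa, x0=x0,
        mode=mode, final_state=to_gametes(h),
    )


def soft_sweep_threshold(params: SweepParams) -> float:
    """kappa = mu_B/s2: below this frequency mutation dominates selection.

    While x < kappa the beneficial allele is pushed up mainly by recurrent
    mutation rather than exponential selective growth; larger kappa means more
    independent mutational origins contribute, hence more multiple-origin soft
    sweeps. kappa = 0 is the hard-sweep (single-origin) regime.
    """
    if params.s2 <= 0:
        raise DomainError("soft_sweep_threshold requires s2 > 0")
    return params.mu_B / params.s2


def kappa_below_deterministic_threshold(params: SweepParams, x0: float) -> bool:
    """Whether kappa = mu_B/s2 lies below the deterministic threshold x0.

    For realistic population sizes and mutation rates kappa < x0 = 5/alpha, so
    the mutation-dominated zone falls inside the stochastic initial phase.
    """
    return soft_sweep_threshold(params) < x0
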