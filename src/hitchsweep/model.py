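"""Core two-locus, two-allele hitchhiking model.

A strongly beneficial allele ``B`` (selection coefficient ``s2 > 0``) sweeps
through a diploid population while a linked locus segregates alleles ``A``/``a``
(selection coefficient ``s1``, possibly deleterious). Fitness is additive,
recombination between the loci occurs at fraction ``r`` per generation, and
both loci mutate recurrently (except ``B -> b``, which is fixed at zero so the
sweep completes).

The module provides the two equivalent deterministic descriptions of the
dynamics:

* gamete coordinates ``(x1, x2, x3, x4)`` — frequencies of AB, aB, Ab, ab —
  with :func:`gamete_rhs`;
* haplotype-structure coordinates ``(x, p1, p2)`` — frequency of B, frequency
  of A among B-bearing and among b-bearing gametes — with :func:`haplo_rhs`;

plus the coordinate changes :func:`to_haplo` / :func:`to_gametes`, linkage
disequilibrium ``D = x1*x4 - x2*x3`` and the locus-A summary statistics.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "EPS_X",
    "SIMPLEX_TOL",
    "ModelAssumptionWarning",
    "InvalidStateError",
    "DomainError",
    "UnsupportedRegimeError",
    "SweepParams",
    "GameteFreqs",
    "HaploState",
    "DiffusionScale",
    "Trajectory",
    "TIME_SCALE_GENERATIONS",
    "TIME_SCALE_DIFFUSION",
    "gamete_rhs",
    "haplo_rhs",
    "to_haplo",
    "to_gametes",
    "linkage_disequilibrium",
    "locus_A_summary",
]

#: Boundary guard for the (p1, p2) chart, which is singular at x = 0 and x = 1.
EPS_X = 1e-12

#: Tolerance for the gamete-frequency simplex constraint x1+x2+x3+x4 = 1.
SIMPLEX_TOL = 1e-9

TIME_SCALE_GENERATIONS = "generations"
TIME_SCALE_DIFFUSION = "diffusion_2N"
_TIME_SCALES = (TIME_SCALE_GENERATIONS, TIME_SCALE_DIFFUSION)


class ModelAssumptionWarning(UserWarning):
    """A parameter combination violates a modelling assumption (not an error)."""


class InvalidStateError(ValueError):
    """A state vector is non-finite or off the frequency simplex."""


class DomainError(ValueError):
    """An input lies outside the mathematical domain of an operation."""


class UnsupportedRegimeError(ValueError):
    """A closed-form solution was requested outside its parameter regime."""


def _require_finite(name: str, *values: float) -> None:
    for v in values:
        if not math.isfinite(v):
            raise InvalidStateError(f"{name} contains a non-finite value: {v!r}")


@dataclass(frozen=True)
class SweepParams:
    """Per-generation rates and coefficients of the two-locus model.

    Parameters
    ----------
    s2
        Selection coefficient of the beneficial allele B. Sweep analyses
        require s2 > 0; s2 = 0 is accepted so the pure-drift and zero-force
        limits of the dynamics remain expressible.
    s1
        Signed selection coefficient at the linked A/a locus. Deleterious A
        (mutation-selection balance) means ``s1 < 0``. The model assumes
        ``|s1|`` is (much) smaller than ``s2``; a warning is emitted otherwise.
    r
        Recombination fraction between the loci, in [0, 0.5].
    mu_A, mu_Abar
        Mutation rates a -> A and A -> a.
    mu_B
        Mutation rate b -> B (the recurrent beneficial mutation).
    mu_Bbar
        Back-mutation B -> b; fixed at 0 so the beneficial allele fixes.
        Any other value is rejected.
    """

    s2: float
    s1: float = 0.0
    r: float = 0.0
    mu_A: float = 0.0
    mu_Abar: float = 0.0
    mu_B: float = 0.0
    mu_Bbar: float = 0.0

    def __post_init__(self) -> None:
        _require_finite(
            "SweepParams",
            self.s1, self.s2, self.r, self.mu_A, self.mu_Abar, self.mu_B, self.mu_Bbar,
        )
        if self.s2 < 0:
            raise ValueError(f"s2 must be >= 0, got {self.s2}")
        if self.mu_Bbar != 0.0:
            raise ValueError("mu_Bbar is fixed at 0 (B -> b back-mutation is excluded)")
        for name in ("mu_A", "mu_Abar", "mu_B"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if not 0.0 <= self.r <= 0.5:
            raise ValueError(f"r must lie in [0, 0.5], got {self.r}")
        if self.s2 > 0 and abs(self.s1) >= self.s2:
            warnings.warn(
                f"|s1| = {abs(self.s1)} is not smaller than s2 = {self.s2}; the model "
                "assumes selection at the linked locus is much weaker than the sweep",
                ModelAssumptionWarning,
                stacklevel=2,
            )

    def as_tuple(self) -> tuple[float, float, float, float, float, float]:
        """(s1, s2, r, mu_A, mu_Abar, mu_B) — handy for hot loops."""
        return (self.s1, self.s2, self.r, self.mu_A, self.mu_Abar, self.mu_B)


@dataclass(frozen=True)
class GameteFreqs:
    """Frequencies of the four gametes AB, aB, Ab, ab."""

    x1: float
    x2: float
    x3: float
    x4: float

    def __post_init__(self) -> None:
        _require_finite("GameteFreqs", self.x1, self.x2, self.x3, self.x4)
        for name in ("x1", "x2", "x3", "x4"):
            v = getattr(self, name)
            if not -SIMPLEX_TOL <= v <= 1.0 + SIMPLEX_TOL:
                raise InvalidStateError(f"{name} = {v} is outside [0, 1]")
        total = self.x1 + self.x2 + self.x3 + self.x4
        if abs(total - 1.0) > SIMPLEX_TOL:
            raise InvalidStateError(f"gamete frequencies sum to {total}, not 1")

    @classmethod
    def from_array(cls, arr: Iterable[float]) -> "GameteFreqs":
        x1, x2, x3, x4 = (float(v) for v in arr)
        return cls(x1, x2, x3, x4)

    def as_array(self) -> np.ndarray:
        return np.array([self.x1, self.x2, self.x3, self.x4])

    @property
    def x(self) -> float:
        """Frequency of the beneficial allele B."""
        return self.x1 + self.x2


@dataclass(frozen=True)
class HaploState:
    """Transformed coordinates (x, p1, p2).

    ``x`` is the frequency of B, ``p1 = x1/x`` the frequency of A among
    B-bearing gametes, ``p2 = x3/(1-x)`` the frequency of A among b-bearing
    gametes. The chart is valid only for 0 < x < 1.
    """

    x: float
    p1: float
    p2: float

    def __post_init__(self) -> None:
        _require_finite("HaploState", self.x, self.p1, self.p2)
        if not EPS_X < self.x < 1.0 - EPS_X:
            raise DomainError(
                f"x = {self.x} is outside the open interval (0, 1); the (p1, p2) "
                "chart is singular at the boundary"
            )
        for name in ("p1", "p2"):
            v = getattr(self, name)
            if not -SIMPLEX_TOL <= v <= 1.0 + SIMPLEX_TOL:
                raise InvalidStateError(f"{name} = {v} is outside [0, 1]")


@dataclass(frozen=True)
class DiffusionScale:
    """Population size and the scaled parameters alpha = 2*N*s2, theta = 4*N*mu_B."""

    N: int
    alpha: float
    theta: float

    def __post_init__(self) -> None:
        if self.N < 1 or int(self.N) != self.N:
            raise ValueError(f"N must be a positive integer, got {self.N}")
        if self.alpha <= 0:
            raise ValueError(f"alpha must be positive, got {self.alpha}")
        if self.theta < 0:
            raise ValueError(f"theta must be >= 0, got {self.theta}")

    @classmethod
    def from_rates(cls, N: int, s2: float, mu_B: float) -> "DiffusionScale":
        """Construct from per-generation rates; the scaling identities hold exactly."""
        return cls(N=N, alpha=2.0 * N * s2, theta=4.0 * N * mu_B)

    @property
    def s2(self) -> float:
        return self.alpha / (2.0 * self.N)

    @property
    def mu_B(self) -> float:
        return self.theta / (4.0 * self.N)


@dataclass
class Trajectory:
    """A time grid with model states and derived observables.

    ``frame`` has columns ``time, x1, x2, x3, x4, x, p1, p2, D, p_A, H``; the
    haplotype-structure columns are NaN where x is 0 or 1 (singular chart).
    ``time_scale`` is either ``"generations"`` or ``"diffusion_2N"`` (time in
    units of 2N generations). ``phase_boundary`` optionally marks the time at
    which a stochastic initial phase hands over to the deterministic phase.
    """

    frame: pd.DataFrame
    time_scale: str
    phase_boundary: float | None = None

    COLUMNS = ("time", "x1", "x2", "x3", "x4", "x", "p1", "p2", "D", "p_A", "H")

    def __post_init__(self) -> None:
        if self.time_scale not in _TIME_SCALES:
            raise ValueError(f"time_scale must be one of {_TIME_SCALES}")
        missing = set(self.COLUMNS) - set(self.frame.columns)
        if missing:
            raise ValueError(f"trajectory frame is missing columns {sorted(missing)}")
        t = self.frame["time"].to_numpy()
        if len(t) == 0:
            raise ValueError("trajectory must contain at least one time point")
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("trajectory times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def times(self) -> np.ndarray:
        return self.frame["time"].to_numpy()

    @classmethod
    def from_haplo(
        cls,
        times: np.ndarray,
        x: np.ndarray,
        p1: np.ndarray,
        p2: np.ndarray,
        time_scale: str = TIME_SCALE_GENERATIONS,
        phase_boundary: float | None = None,
    ) -> "Trajectory":
        times = np.asarray(times, dtype=float)
        x = np.asarray(x, dtype=float)
        p1 = np.clip(np.asarray(p1, dtype=float), 0.0, 1.0)
        p2 = np.clip(np.asarray(p2, dtype=float), 0.0, 1.0)
        x1 = p1 * x
        x2 = (1.0 - p1) * x
        x3 = p2 * (1.0 - x)
        x4 = (1.0 - p2) * (1.0 - x)
        return cls._assemble(times, x1, x2, x3, x4, x, p1, p2, time_scale, phase_boundary)

    @classmethod
    def from_gametes(
        cls,
        times: np.ndarray,
        gametes: np.ndarray,
        time_scale: str = TIME_SCALE_GENERATIONS,
        phase_boundary: float | None = None,
    ) -> "Trajectory":
        """Build from an (n, 4) array of gamete frequencies; p1/p2 are NaN at x in {0,1}."""
        times = np.asarray(times, dtype=float)
        g = np.asarray(gametes, dtype=float)
        x1, x2, x3, x4 = g[:, 0], g[:, 1], g[:, 2], g[:, 3]
        x = x1 + x2
        with np.errstate(divide="ignore", invalid="ignore"):
            p1 = np.where(x > 0, x1 / np.where(x > 0, x, 1.0), np.nan)
            p2 = np.where(x < 1, x3 / np.where(x < 1, 1.0 - x, 1.0), np.nan)
        return cls._assemble(times, x1, x2, x3, x4, x, p1, p2, time_scale, phase_boundary)

    @classmethod
    def _assemble(cls, times, x1, x2, x3, x4, x, p1, p2, time_scale, phase_boundary):
        D = x1 * x4 - x2 * x3
        p_A = x1 + x3
        H = 2.0 * p_A * (1.0 - p_A)
        frame = pd.DataFrame(
            {
                "time": times,
                "x1": x1,
                "x2": x2,
                "x3": x3,
                "x4": x4,
                "x": x,
                "p1": p1,
                "p2": p2,
                "D": D,
                "p_A": p_A,
                "H": H,
            }
        )
        return cls(frame=frame, time_scale=time_scale, phase_boundary=phase_boundary)

    def concat(self, other: "Trajectory") -> "Trajectory":
        """Append a later trajectory segment (same time scale)."""
        if other.time_scale != self.time_scale:
            raise ValueError("cannot concatenate trajectories on different time scales")
        a, b = self.frame, other.frame
        if b["time"].iloc[0] <= a["time"].iloc[-1]:
            b = b[b["time"] > a["time"].iloc[-1]]
        frame = pd.concat([a, b], ignore_index=True)
        return Trajectory(
            frame=frame,
            time_scale=self.time_scale,
            phase_boundary=self.phase_boundary
            if self.phase_boundary is not None
            else other.phase_boundary,
        )


def _gamete_rhs_raw(
    x1: float, x2: float, x3: float, x4: float,
    s1: float, s2: float, r: float, mu_A: float, mu_Abar: float, mu_B: float,
) -> tuple[float, float, float, float]:
    """Plain-float right-hand side; x4 rate by conservation (mu_Bbar = 0)."""
    D = x1 * x4 - x2 * x3
    d1 = (
        -mu_Abar * x1 + mu_A * x2 + mu_B * x3
        + s1 * x1 * (1.0 - x1 - x3)
        + s2 * x1 * (1.0 - x1 - x2)
        - r * D
    )
    d2 = (
        -mu_A * x2 + mu_Abar * x1 + mu_B * x4
        - s1 * x2 * (x1 + x3)
        + s2 * x2 * (1.0 - x1 - x2)
        + r * D
    )
    d3 = (
        -(mu_Abar + mu_B) * x3 + mu_A * x4
        + s1 * x3 * (1.0 - x1 - x3)
        - s2 * x3 * (x1 + x2)
        + r * D
    )
    return d1, d2, d3, -(d1 + d2 + d3)


def gamete_rhs(state: GameteFreqs, params: SweepParams) -> tuple[float, float, float, float]:
    """Rates of change (dx1, dx2, dx3, dx4) in gamete coordinates.

    Selection is additive across loci and acts through the excess of each
    gamete's fitness over the population mean; recombination acts only through
    linkage disequilibrium D = x1*x4 - x2*x3. The x4 rate is returned as
    -(dx1 + dx2 + dx3), so the rates sum to zero exactly.
    """
    return _gamete_rhs_raw(state.x1, state.x2, state.x3, state.x4, *params.as_tuple())


def _haplo_rhs_raw(
    x: float, p1: float, p2: float,
    s1: float, s2: float, r: float, mu_A: float, mu_Abar: float, mu_B: float,
) -> tuple[float, float, float]:
    diff = p1 - p2
    dx = ((s1 * diff + s2) * x + mu_B) * (1.0 - x)
    dp1 = (
        -mu_Abar * p1 + mu_A * (1.0 - p1)
        + s1 * p1 * (1.0 - p1)
        - r * (1.0 - x) * diff
        - mu_B * (1.0 - x) / x * diff
    )
    dp2 = -mu_Abar * p2 + mu_A * (1.0 - p2) + s1 * p2 * (1.0 - p2) + r * x * diff
    return dx, dp1, dp2


def haplo_rhs(state: HaploState, params: SweepParams) -> tuple[float, float, float]:
    """Rates of change (dx, dp1, dp2) in haplotype-structure coordinates.

    The B frequency is driven by direct selection, recurrent mutation, and —
    through D = x(1-x)(p1-p2) — by selection at the linked locus. p1 and p2
    relax toward each other by recombination and by the influx of new B copies
    (at rate mu_B(1-x)/x per B-bearing gamete) sampled from the b background.
    """
    if not EPS_X < state.x < 1.0 - EPS_X:
        raise DomainError(f"x = {state.x} outside (0, 1): transformed chart invalid")
    return _haplo_rhs_raw(state.x, state.p1, state.p2, *params.as_tuple())


def to_haplo(g: GameteFreqs) -> HaploState:
    """Coordinate change (x1..x4) -> (x, p1, p2); requires 0 < x1 + x2 < 1."""
    x = g.x1 + g.x2
    if x <= EPS_X or x >= 1.0 - EPS_X:
        raise DomainError(
            f"x = x1 + x2 = {x} lies on the boundary; p1, p2 are undefined there"
        )
    return HaploState(x=x, p1=g.x1 / x, p2=g.x3 / (1.0 - x))


def to_gametes(h: HaploState) -> GameteFreqs:
    """Inverse coordinate change (x, p1, p2) -> (x1..x4)."""
    return GameteFreqs(
        x1=h.p1 * h.x,
        x2=(1.0 - h.p1) * h.x,
        x3=h.p2 * (1.0 - h.x),
        x4=(1.0 - h.p2) * (1.0 - h.x),
    )


def linkage_disequilibrium(g: GameteFreqs) -> float:
    """D = x1*x4 - x2*x3 (equals x(1-x)(p1-p2) in transformed coordinates)."""
    return g.x1 * g.x4 - g.x2 * g.x3


def locus_A_summary(h: HaploState) -> tuple[float, float]:
    """Frequency p of allele A and heterozygosity H = 2p(1-p) at the linked locus."""
    p = h.p1 * h.x + h.p2 * (1.0 - h.x)
    return p, 2.0 * p * (1.0 - p)
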