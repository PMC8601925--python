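"""Discrete-generation two-locus Wright-Fisher forward simulator.

The brute-force stochastic counterpart of the deterministic model: each
generation applies one Euler step of the full gamete ODE right-hand side
(selection, mutation and recombination jointly — valid to first order because
all per-generation rates are << 1) and then resamples 2N gametes
multinomially. It serves three purposes:

* oracle for the diffusion moments of the initial phase;
* measurement of first-hitting times of the deterministic threshold x0;
* classification of completed sweeps as hard or multiple-origin soft, as a
  function of kappa = mu_B/s2.

A sweep ends at the first generation with x >= 1 - x0; it is a
multiple-origin soft sweep if at that moment both the AB and the aB gamete
exceed the detection threshold epsilon (default 5%), i.e. beneficial copies
from both mutational backgrounds are simultaneously common.

All randomness flows from the config seed through per-replicate
``numpy.random.SeedSequence`` substreams, so every output is reproducible
bit for bit.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .model import (
    GameteFreqs,
    ModelAssumptionWarning,
    SweepParams,
    Trajectory,
    _gamete_rhs_raw,
)

__all__ = [
    "SimConfig",
    "SweepOutcome",
    "EnsembleStats",
    "ParameterMagnitudeError",
    "wf_step",
    "run_replicate",
    "ensemble_stats",
    "softness_scan",
    "selection_scan",
]

NO_SWEEP = "no_sweep"
HARD = "hard"
SOFT = "multiple_origin_soft"


class ParameterMagnitudeError(ValueError):
    """Per-generation rates too large for the one-Euler-step life cycle."""


@dataclass(frozen=True)
class SimConfig:
    """Configuration of a Wright-Fisher run.

    ``x0`` is the deterministic threshold used for hitting times and the sweep
    endpoint 1 - x0; ``None`` resolves to 5/alpha = 2.5/(N s2). ``epsilon`` is
    the soft-sweep detection threshold applied to x1 and x2 at sweep end.
    """

    params: SweepParams
    N: int
    init: GameteFreqs
    seed: int
    max_generations: int = 200_000
    record_every: int = 1
    x0: float | None = None
    epsilon: float = 0.05

    def __post_init__(self) -> None:
        if self.N < 10:
            raise ValueError(f"N must be >= 10, got {self.N}")
        if self.max_generations < 1:
            raise ValueError("max_generations must be >= 1")
        if self.record_every < 1:
            raise ValueError("record_every must be >= 1")
        if not isinstance(self.seed, (int, np.integer)):
            raise TypeError("seed is mandatory and must be an integer")
        if self.x0 is not None and not 0.0 < self.x0 < 0.5:
            raise ValueError(f"x0 = {self.x0} must lie in (0, 0.5)")

    @property
    def resolved_x0(self) -> float:
        return self.x0 if self.x0 is not None else 2.5 / (self.N * self.params.s2)


@dataclass(frozen=True)
class SweepOutcome:
    """Result of a single replicate."""

    swept: bool
    classification: str
    final: GameteFreqs
    hitting_time_x0: int | None
    completion_time: int | None

    def __post_init__(self) -> None:
        if self.classification not in (NO_SWEEP, HARD, SOFT):
            raise ValueError(f"unknown classification {self.classification!r}")
        if self.classification != NO_SWEEP and not self.swept:
            raise ValueError("classified sweeps must have swept=True")


def _expected_next(freqs, pt):
    """One Euler step of the full right-hand side, clipped to the simplex."""
    x1, x2, x3, x4 = freqs
    d1, d2, d3, d4 = _gamete_rhs_raw(x1, x2, x3, x4, *pt)
    e1, e2, e3, e4 = x1 + d1, x2 + d2, x3 + d3, x4 + d4
    low = min(e1, e2, e3, e4)
    if low < -1e-6:
        raise ParameterMagnitudeError(
            f"expected frequencies left the simplex by {low}; per-generation "
            "rates are too large for the Euler life cycle"
        )
    e1, e2, e3, e4 = max(e1, 0.0), max(e2, 0.0), max(e3, 0.0), max(e4, 0.0)
    s = e1 + e2 + e3 + e4
    return e1 / s, e2 / s, e3 / s, e4 / s


def wf_step(
    g: GameteFreqs, params: SweepParams, N: int, rng: np.random.Generator | None
) -> GameteFreqs:
    """One Wright-Fisher generation: deterministic update, then resampling.

    The realized next-generation frequencies are a multinomial sample of 2N
    gametes from the expected frequencies. Passing ``rng=None`` skips the
    sampling and returns the expectation itself (the N -> infinity surrogate).
    """
    expected = _expected_next((g.x1, g.x2, g.x3, g.x4), params.as_tuple())
    if rng is None:
        return GameteFreqs(*expected)
    counts = rng.multinomial(2 * N, expected)
    two_N = 2 * N
    return GameteFreqs(*(c / two_N for c in counts))


def _evolve_until(
    cfg: SimConfig,
    *,
    target_x: float | None = None,
    sweep_end_x: float | None = None,
    record_gens: tuple[int, ...] = (),
    rng: np.random.Generator | None = None,
):
    """Internal engine: evolve until a frequency target, recording on the way.

    Returns (recorded_times, recorded_states, hit_gen, end_gen, end_state)
    where hit_gen is the first generation with x >= target_x (if requested)
    and end_gen the first with x >= sweep_end_x. ``record_gens`` are extra
    generations whose states are stored in the returned dict keyed by
    generation (attached as the last element when non-empty).
    """
    if rng is None:
        rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(cfg.seed)))
    pt = cfg.params.as_tuple()
    two_N = 2 * cfg.N
    freqs = (cfg.init.x1, cfg.init.x2, cfg.init.x3, cfg.init.x4)
    rec_t = [0]
    rec_g = [freqs]
    hit_gen = None
    end_gen = None
    hit_state = None
    multinomial = rng.multinomial
    stop_gen = cfg.max_generations
    for gen in range(1, stop_gen + 1):
        expected = _expected_next(freqs, pt)
        counts = multinomial(two_N, expected)
        freqs = (
            counts[0] / two_N, counts[1] / two_N, counts[2] / two_N, counts[3] / two_N,
        )
        x = freqs[0] + freqs[1]
        if gen % cfg.record_every == 0:
            rec_t.append(gen)
            rec_g.append(freqs)
        if hit_gen is None and target_x is not None and x >= target_x:
            hit_gen = gen
            hit_state = freqs
            if sweep_end_x is None:
                break
        if sweep_end_x is not None and x >= sweep_end_x:
            end_gen = gen
            break
    if rec_t[-1] != (end_gen or hit_gen or stop_gen):
        last = end_gen if end_gen is not None else (hit_gen if hit_gen is not None else stop_gen)
        if last > rec_t[-1]:
            rec_t.append(last)
            rec_g.append(freqs)
    return rec_t, rec_g, hit_gen, end_gen, (hit_state if hit_state is not None else freqs)


def _classify(freqs, epsilon: float) -> str:
    x1, x2 = freqs[0], freqs[1]
    if x1 > epsilon and x2 > epsilon:
        return SOFT
    return HARD


def run_replicate(cfg: SimConfig) -> tuple[SweepOutcome, Trajectory]:
    """Run one replicate to sweep completion (x >= 1 - x0) or the cap.

    Classification happens at the first generation with x >= 1 - x0 (the end
    of the selective phase), not at absolute fixation, to match the
    deterministic sweep duration and avoid long neutral tails.
    """
    x0 = cfg.resolved_x0
    rec_t, rec_g, hit_gen, end_gen, final = _evolve_until(
        cfg, target_x=x0, sweep_end_x=1.0 - x0
    )
    traj = Trajectory.from_gametes(np.asarray(rec_t, float), np.asarray(rec_g))
    if end_gen is None:
        outcome = SweepOutcome(
            swept=False, classification=NO_SWEEP, final=GameteFreqs(*final),
            hitting_time_x0=hit_gen, completion_time=None,
        )
    else:
        outcome = SweepOutcome(
            swept=True, classification=_classify(final, cfg.epsilon),
            final=GameteFreqs(*final), hitting_time_x0=hit_gen, completion_time=end_gen,
        )
    return outcome, traj


@dataclass(frozen=True)
class EnsembleStats:
    """Per-time-point ensemble moments with Monte-Carlo standard errors."""

    table: pd.DataFrame
    reps: int
    mean_hitting_time: float | None
    se_hitting_time: float | None
    n_hit: int
    n_swept: int | None = None
    n_soft: int | None = None

    @property
    def prop_soft(self) -> float | None:
        if self.n_swept is None or self.n_swept == 0:
            return None
        return self.n_soft / self.n_swept


def _substream(seed: int, *indices: int) -> np.random.Generator:
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence([seed, *indices])))


def ensemble_stats(
    cfg: SimConfig,
    reps: int,
    t_points: tuple[int, ...],
    *,
    classify: bool = False,
) -> EnsembleStats:
    """Ensemble moments of x and x1 at given generations, plus hitting times.

    Each replicate runs on its own deterministic substream derived from
    (seed, replicate index). Replicates run until all ``t_points`` are
    recorded and x has hit x0 (or, with ``classify=True``, until sweep end so
    hard/soft proportions can be reported). Standard errors of the variances
    use the empirical fourth moment.
    """
    if reps < 2:
        raise ValueError("reps must be >= 2")
    t_points = tuple(sorted(int(t) for t in t_points))
    x0 = cfg.resolved_x0
    pt = cfg.params.as_tuple()
    two_N = 2 * cfg.N
    g0 = (cfg.init.x1, cfg.init.x2, cfg.init.x3, cfg.init.x4)

    xs = np.full((reps, len(t_points)), np.nan)
    x1s = np.full((reps, len(t_points)), np.nan)
    hits = np.full(reps, np.nan)
    n_swept = 0
    n_soft = 0

    for rep in range(reps):
        rng = _substream(cfg.seed, rep)
        multinomial = rng.multinomial
        freqs = g0
        hit = None
        ended = False
        k = 0
        for gen in range(1, cfg.max_generations + 1):
            expected = _expected_next(freqs, pt)
            counts = multinomial(two_N, expected)
            freqs = (
                counts[0] / two_N, counts[1] / two_N,
                counts[2] / two_N, counts[3] / two_N,
            )
            x = freqs[0] + freqs[1]
            if k < len(t_points) and gen == t_points[k]:
                xs[rep, k] = x
                x1s[rep, k] = freqs[0]
                k += 1
            if hit is None and x >= x0:
                hit = gen
            if classify and not ended and x >= 1.0 - x0:
                n_swept += 1
                if _classify(freqs, cfg.epsilon) == SOFT:
                    n_soft += 1
                ended = True
            if k == len(t_points) and hit is not None and (ended or not classify):
                break
        if hit is not None:
            hits[rep] = hit

    rows = []
    for k, t in enumerate(t_points):
        for name, a in (("x", xs[:, k]), ("x1", x1s[:, k])):
            mean = a.mean()
            var = a.var(ddof=1)
            m4 = ((a - mean) ** 4).mean()
            rows.append(
                {
                    "generation": t,
                    "variable": name,
                    "mean": mean,
                    "var": var,
                    "se_mean": math.sqrt(var / reps),
                    "se_var": math.sqrt(max(m4 - var**2, 0.0) / reps),
                }
            )
    table = pd.DataFrame(rows)
    hit_vals = hits[~np.isnan(hits)]
    n_hit = len(hit_vals)
    mean_hit = float(hit_vals.mean()) if n_hit else None
    se_hit = float(hit_vals.std(ddof=1) / math.sqrt(n_hit)) if n_hit > 1 else None
    return EnsembleStats(
        table=table, reps=reps, mean_hitting_time=mean_hit, se_hitting_time=se_hit,
        n_hit=n_hit, n_swept=(n_swept if classify else None),
        n_soft=(n_soft if classify else None),
    )


def _scan_point(cfg: SimConfig, reps: int, stream_index: int) -> dict:
    """Run `reps` replicates to sweep end; count soft sweeps."""
    x0 = cfg.resolved_x0
    end_x = 1.0 - x0
    pt = cfg.params.as_tuple()
    two_N = 2 * cfg.N
    g0 = (cfg.init.x1, cfg.init.x2, cfg.init.x3, cfg.init.x4)
    n_swept = 0
    n_soft = 0
    for rep in range(reps):
        rng = _substream(cfg.seed, stream_index, rep)
        multinomial = rng.multinomial
        freqs = g0
        for gen in range(1, cfg.max_generations + 1):
            expected = _expected_next(freqs, pt)
            counts = multinomial(two_N, expected)
            freqs = (
                counts[0] / two_N, counts[1] / two_N,
                counts[2] / two_N, counts[3] / two_N,
            )
            if freqs[0] + freqs[1] >= end_x:
                n_swept += 1
                if _classify(freqs, cfg.epsilon) == SOFT:
                    n_soft += 1
                break
    prop = n_soft / n_swept if n_swept else 0.0
    se = math.sqrt(prop * (1.0 - prop) / n_swept) if n_swept else float("nan")
    return {
        "n_reps": reps, "n_swept": n_swept, "n_soft": n_soft,
        "prop_soft": prop, "prop_swept": n_swept / reps, "se": se,
    }


def softness_scan(
    base: SimConfig, kappa_grid, reps: int
) -> pd.DataFrame:
    """Proportion of multiple-origin soft sweeps along a kappa = mu_B/s2 grid.

    kappa is varied through mu_B at fixed s2, so theta = 4 N mu_B co-varies
    with kappa. The soft proportion (among completed sweeps) is expected to be
    non-decreasing in kappa: a larger mutational supply makes a second origin
    on the other background more likely before the first fixes.
    """
    rows = []
    for i, kappa in enumerate(kappa_grid):
        if kappa < 0:
            raise ValueError("kappa must be >= 0")
        mu_B = kappa * base.params.s2
        theta = 4.0 * base.N * mu_B
        if theta > 10.0:
            warnings.warn(
                f"theta = {theta:.3g} > 10 at kappa = {kappa}: outside the "
                "biologically plausible range",
                ModelAssumptionWarning,
                stacklevel=2,
            )
        params = replace(base.params, mu_B=mu_B)
        cfg = replace(base, params=params)
        if kappa == 0 and base.init.x == 0.0:
            # B can never arise: soft proportion is exactly 0 by construction.
            row = {"n_reps": reps, "n_swept": 0, "n_soft": 0, "prop_soft": 0.0,
                   "prop_swept": 0.0, "se": float("nan")}
        else:
            row = _scan_point(cfg, reps, i)
        rows.append({"kappa": kappa, "theta": theta, **row})
    return pd.DataFrame(rows)


def selection_scan(
    base: SimConfig, s2_grid, reps: int
) -> pd.DataFrame:
    """Soft-sweep proportion along an s2 grid at fixed mu_B.

    The complementary axis to :func:`softness_scan`: stronger selection
    shortens the fixation time of the first origin and lowers kappa, so the
    soft proportion should be non-increasing in s2.
    """
    rows = []
    for i, s2 in enumerate(s2_grid):
        params = replace(base.params, s2=s2)
        cfg = replace(base, params=params)
        row = _scan_point(cfg, reps, 1000 + i)
        rows.append(
            {"s2": s2, "kappa": params.mu_B / s2, "theta": 4.0 * base.N * params.mu_B, **row}
        )
    return pd.DataFrame(rows)
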