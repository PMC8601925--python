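"""Shared fixtures and random-state helpers for the test suite."""

import numpy as np
import pytest

from hitchsweep import GameteFreqs, SweepParams


def random_gametes(rng: np.random.Generator, x_min: float = 0.01, x_max: float = 0.99) -> GameteFreqs:
    """A random simplex point whose B frequency lies inside (x_min, x_max)."""
    while True:
        g = rng.dirichlet(np.ones(4))
        if x_min < g[0] + g[1] < x_max:
            return GameteFreqs(*g)


def random_params(rng: np.random.Generator) -> SweepParams:
    """A random parameter set with |s1| < s2 and realistic rate magnitudes."""
    s2 = rng.uniform(1e-3, 0.1)
    return SweepParams(
        s2=s2,
        s1=rng.uniform(-0.5, 0.5) * s2,
        r=rng.uniform(0.0, 0.5),
        mu_A=rng.uniform(0.0, 1e-3),
        mu_Abar=rng.uniform(0.0, 1e-3),
        mu_B=rng.uniform(0.0, 1e-3),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1)
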