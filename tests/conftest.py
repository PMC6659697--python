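"""Shared fixtures: small seeded landscapes and pre-built case-control tables.

Everything is generated programmatically; nothing is read from disk.
"""

from __future__ import annotations

import numpy as np
import pytest

import stepselect as ss


@pytest.fixture(scope="session")
def small_stack() -> ss.LandscapeStack:
    """A 2.4 x 1.8 km landscape at 30 m, sized for exhaustive oracles."""
    cfg = ss.LandscapeConfig(
        extent_m=(2400.0, 1800.0),
        resolution_m=30.0,
        seed=42,
        pa_count=3,
        pa_mean_area_m2=6.0e4,
    )
    return ss.generate_landscape(cfg)


@pytest.fixture(scope="session")
def default_stack() -> ss.LandscapeStack:
    """The default 15 x 9 km landscape used by the simulation experiments."""
    return ss.generate_landscape(ss.LandscapeConfig(seed=7))


@pytest.fixture(scope="session")
def null_steps(default_stack) -> "pd.DataFrame":
    """Step series of one long null-framework track."""
    track = ss.simulate_track(
        default_stack,
        ss.MovementParams(),
        ss.SelectionParams(),
        n_fixes=5000,
        seed=11,
        individual_id="null0",
    )
    return ss.derive_steps(track)


@pytest.fixture(scope="session")
def small_table(small_stack) -> "pd.DataFrame":
    """A complete scaled case-control table from a short simulated track."""
    track = ss.simulate_track(
        small_stack,
        ss.MovementParams(),
        ss.SelectionParams(),
        n_fixes=220,
        seed=5,
        individual_id="ind0",
    )
    steps = ss.derive_steps(track)
    dist = ss.fit_step_distribution(steps)
    geom = ss.generate_available(steps, dist, k=10, seed=6, stack=small_stack)
    table = ss.attach_covariates(geom, small_stack)
    return ss.scale_covariates(table)


def softmax_design(rng, n_strata, stratum_size, beta):
    """Simulate a case-control design directly from the clogit model."""
    p = len(beta)
    n = n_strata * stratum_size
    X = rng.standard_normal((n, p))
    strata = np.repeat(np.arange(n_strata), stratum_size)
    y = np.zeros(n, dtype=int)
    for s in range(n_strata):
        block = slice(s * stratum_size, (s + 1) * stratum_size)
        u = X[block] @ np.asarray(beta)
        pr = np.exp(u - u.max())
        pr /= pr.sum()
        y[s * stratum_size + rng.choice(stratum_size, p=pr)] = 1
    terms = [f"x{j}" for j in range(p)]
    return ss.DesignMatrix(X=X, y=y, strata=strata, terms=terms)
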