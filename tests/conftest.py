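"""Shared fixtures: reference ensembles and the homogenization sweep.

The heavy session-scoped fixtures mirror the reference study conditions
(L = 5, D0 = 1, lambda = 0.2, midpoint start) at ensemble size N = 10^4,
and are shared across the statistical tests so each is simulated once.
"""

from __future__ import annotations

import numpy as np
import pytest

import crowddiff as cd


@pytest.fixture(scope="session")
def homog_curve():
    """Unit-cell sweep over rho = 0, 0.04, ..., 0.92 at n = 64."""
    rhos = np.arange(0.0, 0.9201, 0.04)
    return cd.sweep(rhos, n=64)


@pytest.fixture(scope="session")
def wiener_06():
    cfg = cd.WalkConfig(model="wiener", rho=0.6, n_walks=10_000, seed=11)
    return cd.simulate_wiener(cfg)


@pytest.fixture(scope="session")
def wiener_10():
    cfg = cd.WalkConfig(model="wiener", rho=1.0, n_walks=10_000, seed=12)
    return cd.simulate_wiener(cfg)


@pytest.fixture(scope="session")
def kinetic_06():
    cfg = cd.WalkConfig(model="kinetic", rho=0.6, n_walks=10_000, seed=13)
    return cd.simulate_kinetic(cfg)


@pytest.fixture(scope="session")
def wiener_06_half_dt(wiener_06):
    base = wiener_06.config
    cfg = cd.WalkConfig(
        model="wiener", rho=0.6, n_walks=10_000, seed=14, dt=base.dt_value / 2.0
    )
    return cd.simulate_wiener(cfg)


@pytest.fixture(scope="session")
def kinetic_06_half_lambda():
    cfg = cd.WalkConfig(model="kinetic", rho=0.6, lam=0.10, n_walks=10_000, seed=15)
    return cd.simulate_kinetic(cfg)


@pytest.fixture(scope="session")
def species():
    return cd.geometry.load_library()
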