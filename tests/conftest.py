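"""Shared fixtures: lattices, synthetic studies, and a cached replicate set
of parameter-recovery fits reused by the slower statistical checks."""

from __future__ import annotations

import numpy as np
import pytest

from lifespan.sdem import fit_sdem
from lifespan.synthetic import (
    LatticeConfig,
    TrueParameters,
    lattice_weights,
    make_fixture,
    simulate_covariates,
    simulate_sdem_outcome,
)

RECOVERY_TRUTH = TrueParameters(
    alpha=80.75, beta=(1.0, -0.5), theta=(0.3, 0.0), lam=0.5, sigma=1.0
)
N_RECOVERY_SEEDS = 50


@pytest.fixture(scope="session")
def grid5_weights():
    return lattice_weights(LatticeConfig(rows=5, cols=5, seed=0))


@pytest.fixture(scope="session")
def grid10_weights():
    return lattice_weights(LatticeConfig(rows=10, cols=10, seed=0))


@pytest.fixture(scope="session")
def recovery_lattice():
    cfg = LatticeConfig(rows=30, cols=30, seed=7, covariate_count=2)
    return cfg, lattice_weights(cfg)


@pytest.fixture(scope="session")
def recovery_fits(recovery_lattice):
    """50 seeded replicate SDEM fits on the 30x30 lattice with known truth.

    Returns (truth, list of (fit, W)); shared across the recovery,
    coverage and residual-autocorrelation checks so the simulation runs
    once per session.
    """
    cfg, W = recovery_lattice
    fits = []
    for seed in range(1, N_RECOVERY_SEEDS + 1):
        rng = np.random.default_rng(seed)
        X = simulate_covariates(cfg, W, rng)
        y = simulate_sdem_outcome(X, W, RECOVERY_TRUTH, rng)
        fits.append(fit_sdem(y.to_numpy(), X, W))
    return RECOVERY_TRUTH, fits, W


@pytest.fixture(scope="session")
def tiny_fixture_dir(tmp_path_factory):
    d = tmp_path_factory.mktemp("tiny")
    make_fixture("tiny", d)
    return d


@pytest.fixture(scope="session")
def filterable_fixture_dir(tmp_path_factory):
    d = tmp_path_factory.mktemp("filterable")
    make_fixture("filterable", d)
    return d
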