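"""Synthetic tract studies with the statistical structure the pipeline assumes.

Everything is generated on a rows x cols lattice of unit-square tracts
under queen contiguity, so no external data are needed:

* covariates follow a spatial autoregressive process
  x_j = (I - rho_x W)^{-1} eta_j, standardized to mean 0 / variance 1;
* the outcome (life expectancy, years) follows the same spatial Durbin
  error process the estimator fits:
  y = alpha + X beta + W X theta + u, u = (I - lambda W)^{-1} eps;
* mortality counts follow a Gompertz baseline hazard
  m(age) = a exp(b age), scaled per tract by exp(x' delta), with
  person-years from a fixed age pyramid and Poisson death draws.

Two outcome modes exist by design: "direct" (y drawn from the SDEM
equation — sharp parameter-recovery tests) and "mechanistic" (y = e0
computed from the simulated mortality — end-to-end realism, attenuated
effects).

`make_fixture` bundles named desk-scale studies ("tiny", "recovery",
"filterable") to disk with a truth JSON recording every parameter and
seed, so the full pipeline is testable and reproducible offline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .lifetable import AgeSchedule, TractMortality, build_default_age_schedule
from .weights import (
    SpatialWeights,
    grid_queen_contiguity,
    row_standardize,
    write_gal,
)

__all__ = [
    "LatticeConfig",
    "TrueParameters",
    "MortalitySimConfig",
    "DEFAULT_AGE_PYRAMID",
    "simulate_covariates",
    "simulate_sdem_outcome",
    "simulate_mortality",
    "expected_mortality",
    "lattice_weights",
    "grid_geojson",
    "make_fixture",
    "FIXTURES",
]


@dataclass(frozen=True)
class LatticeConfig:
    rows: int = 10
    cols: int = 10
    seed: int = 0
    covariate_count: int = 2
    covariate_autocorrelation: float = 0.4

    def __post_init__(self) -> None:
        if self.rows * self.cols < 9:
            raise ValueError("lattice needs at least 9 tracts")
        if self.covariate_count < 1:
            raise ValueError("need at least one covariate")
        if not -1.0 < self.covariate_autocorrelation < 1.0:
            raise ValueError("covariate autocorrelation must lie in (-1, 1)")


@dataclass(frozen=True)
class TrueParameters:
    """Generating parameters of the SDEM outcome equation."""

    alpha: float = 80.75  # years; a realistic tract-level LE intercept
    beta: tuple[float, ...] = (1.0, -0.5)
    theta: tuple[float, ...] = (0.3, 0.0)
    lam: float = 0.5
    sigma: float = 1.0

    def __post_init__(self) -> None:
        if not -1.0 < self.lam < 1.0:
            raise ValueError("lambda must lie in (-1, 1)")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if len(self.beta) != len(self.theta):
            raise ValueError("beta and theta must have equal length")


# Person-year shares per 19-interval age group: more exposure at younger
# ages, tapering after 65.  A fixture constant, not a demographic claim.
DEFAULT_AGE_PYRAMID: np.ndarray = np.array(
    [
        0.012, 0.048, 0.062, 0.064, 0.066, 0.066, 0.064, 0.064,
        0.064, 0.068, 0.072, 0.072, 0.066, 0.058, 0.048, 0.038,
        0.028, 0.022, 0.018,
    ]
)
assert abs(DEFAULT_AGE_PYRAMID.sum() - 1.0) < 1e-12


@dataclass(frozen=True)
class MortalitySimConfig:
    """Gompertz-baseline Poisson mortality on top of the covariate surface."""

    gompertz_a: float = 5e-5  # hazard per person-year at age 0
    gompertz_b: float = 0.085  # log-hazard slope per year of age
    covariate_log_rate_effects: tuple[float, ...] = (0.1, 0.05)
    base_population_per_tract: float = 4000.0
    study_years: int = 5
    open_interval_midpoint: float = 90.0

    def __post_init__(self) -> None:
        if self.gompertz_a <= 0 or self.gompertz_b <= 0:
            raise ValueError("Gompertz parameters must be positive")
        if self.base_population_per_tract < 0:
            raise ValueError("population must be non-negative")


def lattice_weights(cfg: LatticeConfig) -> SpatialWeights:
    """Row-standardized queen weights of the configured lattice."""
    return row_standardize(grid_queen_contiguity(cfg.rows, cfg.cols))


def simulate_covariates(
    cfg: LatticeConfig, W: SpatialWeights, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Spatially autocorrelated covariates, standardized column-wise.

    Each column solves x = (I - rho W)^{-1} eta with iid standard-normal
    eta, then is centered and scaled to unit variance.
    """
    rho = cfg.covariate_autocorrelation
    ev = W.eigenvalues
    if not (1.0 / ev.min() < rho < 1.0 / ev.max()):
        raise ValueError(f"autocorrelation {rho} inadmissible for this lattice")
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    n = W.n
    A = np.eye(n) - rho * W.dense()
    eta = rng.standard_normal((n, cfg.covariate_count))
    X = np.linalg.solve(A, eta)
    X = (X - X.mean(axis=0)) / X.std(axis=0)
    return pd.DataFrame(
        X, index=list(W.ids), columns=[f"x{j + 1}" for j in range(cfg.covariate_count)]
    )


def simulate_sdem_outcome(
    X: pd.DataFrame,
    W: SpatialWeights,
    params: TrueParameters,
    seed: int | np.random.Generator = 0,
) -> pd.Series:
    """Outcome drawn from the spatial Durbin error process."""
    ev = W.eigenvalues
    if not (1.0 / ev.min() < params.lam < 1.0):
        raise ValueError(f"lambda {params.lam} makes I - lambda W singular")
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    n = W.n
    Xm = X.to_numpy(dtype=float)
    beta = np.asarray(params.beta)
    theta = np.asarray(params.theta)
    if Xm.shape[1] != beta.shape[0]:
        raise ValueError("covariate count does not match beta/theta length")
    eps = rng.standard_normal(n) * params.sigma
    u = np.linalg.solve(np.eye(n) - params.lam * W.dense(), eps)
    y = params.alpha + Xm @ beta + (W.weights @ Xm) @ theta + u
    return pd.Series(y, index=X.index, name="life_expectancy")


def _interval_midpoints(schedule: AgeSchedule, open_midpoint: float) -> np.ndarray:
    mids = []
    for iv in schedule.intervals:
        if iv.is_open:
            mids.append(open_midpoint)
        else:
            mids.append(iv.start_age + iv.width / 2.0)
    return np.array(mids)


def expected_mortality(
    X: pd.DataFrame, cfg: MortalitySimConfig, schedule: AgeSchedule | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Expected deaths and person-years per tract x interval (no sampling).

    Rates follow m_ia = a exp(b * midpoint_age) * exp(x_i' delta); the
    open interval uses a fixed midpoint age to close the schedule.
    """
    if schedule is None:
        schedule = build_default_age_schedule()
    mids = _interval_midpoints(schedule, cfg.open_interval_midpoint)
    base_rate = cfg.gompertz_a * np.exp(cfg.gompertz_b * mids)  # per interval
    delta = np.asarray(cfg.covariate_log_rate_effects, dtype=float)
    Xm = X.to_numpy(dtype=float)
    if Xm.shape[1] != delta.shape[0]:
        raise ValueError("covariate count does not match delta length")
    tract_scale = np.exp(Xm @ delta)  # per tract
    py = (
        DEFAULT_AGE_PYRAMID[None, :]
        * cfg.base_population_per_tract
        * cfg.study_years
    ) * np.ones((Xm.shape[0], 1))
    expected = tract_scale[:, None] * base_rate[None, :] * py
    return expected, py


def simulate_mortality(
    X: pd.DataFrame,
    cfg: MortalitySimConfig,
    schedule: AgeSchedule | None = None,
    seed: int | np.random.Generator = 0,
) -> list[TractMortality]:
    """Poisson death counts around the Gompertz expectation, per tract."""
    if schedule is None:
        schedule = build_default_age_schedule()
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    expected, py = expected_mortality(X, cfg, schedule)
    deaths = rng.poisson(expected)
    return [
        TractMortality(str(tid), deaths[i].astype(float), py[i])
        for i, tid in enumerate(X.index)
    ]


def grid_geojson(rows: int, cols: int) -> dict:
    """Unit-square lattice as a GeoJSON FeatureCollection (ids match the grid)."""
    features = []
    for r in range(rows):
        for c in range(cols):
            ring = [
                [c, r], [c + 1, r], [c + 1, r + 1], [c, r + 1], [c, r]
            ]
            features.append(
                {
                    "type": "Feature",
                    "properties": {"tract_id": f"r{r:03d}c{c:03d}"},
                    "geometry": {"type": "Polygon", "coordinates": [ring]},
                }
            )
    return {"type": "FeatureCollection", "features": features}


# ---------------------------------------------------------------------------
# Named fixtures


def _engineered_bad_tracts(schedule: AgeSchedule, study_years: int = 5) -> list[dict]:
    """Deterministic tracts hitting each reliability criterion exactly.

    All closed-interval deaths are zero, so the e0 standard error equals
    the open-interval term 1/(m sqrt(D)) exactly and each screen fires
    (or passes at its boundary) by construction.  Populations are
    integers per interval so person-year totals survive the CSV
    population round-trip exactly — the boundary tracts sit on their
    thresholds to the last bit.
    """
    k = len(schedule)

    def tract(name, open_deaths, open_pop, closed_pop_per_interval):
        deaths = np.zeros(k)
        deaths[-1] = open_deaths
        py = np.empty(k)
        py[:-1] = closed_pop_per_interval * study_years
        py[-1] = open_pop * study_years
        return {"name": name, "deaths": deaths, "py": py}

    return [
        # fails (a): 49 deaths; m_open = 49/490 = 0.1, SE = 1/(0.1 sqrt(49))
        # = 1.43 <= 2; PY = 9900 + 490
        tract("bad_deaths", 49, 98, 110),
        # fails (b): PY = 4410 + 500 = 4910 < 5000; 100 deaths; SE = 0.5
        tract("bad_person_years", 100, 100, 49),
        # fails (c): SE = 1/((55/1100) sqrt(55)) = 2.70 > 2; PY = 5060
        tract("bad_se", 55, 220, 44),
        # boundary passes: exactly 50 deaths, SE = 1.41, PY = 10400
        tract("edge_deaths", 50, 100, 110),
        # boundary passes: exactly 5000 PY (4500 + 500), 100 deaths, SE = 0.5
        tract("edge_person_years", 100, 100, 50),
        # boundary passes: SE exactly 2.0 = 1/(0.05 sqrt(100)); PY = 5600
        tract("edge_se", 100, 400, 40),
    ]


FIXTURES = ("tiny", "recovery", "filterable")


def make_fixture(name: str, outdir: str | Path) -> Path:
    """Write a named synthetic study (CSV + GeoJSON + GAL + truth JSON).

    tiny        5x5 lattice, quick end-to-end smoke material.
    recovery    30x30 lattice with known SDEM parameters for recovery tests.
    filterable  6x6 lattice whose last six tracts are engineered to fail
                (or sit exactly on) each reliability criterion.
    """
    if name not in FIXTURES:
        raise ValueError(f"unknown fixture {name!r}; known: {FIXTURES}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    schedule = build_default_age_schedule()

    if name == "tiny":
        lattice = LatticeConfig(rows=5, cols=5, seed=11, covariate_count=2)
        params = TrueParameters()
        # large tracts so every simulated tract clears the reliability
        # screen; engineered failures live in the "filterable" fixture
        mort_cfg = MortalitySimConfig(base_population_per_tract=12_000.0)
    elif name == "recovery":
        lattice = LatticeConfig(rows=30, cols=30, seed=7, covariate_count=2)
        params = TrueParameters(
            alpha=80.75, beta=(1.0, -0.5), theta=(0.3, 0.0), lam=0.5, sigma=1.0
        )
        mort_cfg = MortalitySimConfig()
    else:  # filterable
        lattice = LatticeConfig(rows=6, cols=6, seed=23, covariate_count=2)
        params = TrueParameters()
        mort_cfg = MortalitySimConfig(base_population_per_tract=8000.0)

    W = lattice_weights(lattice)
    rng = np.random.default_rng(lattice.seed)
    X = simulate_covariates(lattice, W, rng)
    y = simulate_sdem_outcome(X, W, params, rng)
    mortality = simulate_mortality(X, mort_cfg, schedule, rng)

    engineered: dict[str, str] = {}
    if name == "filterable":
        bad = _engineered_bad_tracts(schedule)
        ids = list(X.index)
        for spec_row, tid in zip(bad, ids[-len(bad):]):
            i = ids.index(tid)
            mortality[i] = TractMortality(tid, spec_row["deaths"], spec_row["py"])
            engineered[tid] = spec_row["name"]

    k = len(schedule)
    dcols = [f"d_{i:02d}" for i in range(k)]
    pcols = [f"p_{i:02d}" for i in range(k)]
    mort_df = pd.DataFrame(
        [t.deaths for t in mortality], index=[t.tract_id for t in mortality],
        columns=dcols,
    )
    # population CSV stores census-style population counts (PY / study years)
    pop_df = pd.DataFrame(
        [t.person_years / mort_cfg.study_years for t in mortality],
        index=[t.tract_id for t in mortality],
        columns=pcols,
    )
    mort_df.rename_axis("tract_id").to_csv(outdir / "mortality.csv")
    pop_df.rename_axis("tract_id").to_csv(outdir / "population.csv")

    cov = X.copy()
    cov["life_expectancy"] = y
    cov.rename_axis("tract_id").to_csv(outdir / "covariates.csv")

    with open(outdir / "tracts.geojson", "w") as fh:
        json.dump(grid_geojson(lattice.rows, lattice.cols), fh, sort_keys=True)
    write_gal(W.adjacency, outdir / "tracts.gal")

    truth = {
        "fixture": name,
        "lattice": asdict(lattice),
        "true_parameters": {
            "alpha": params.alpha,
            "beta": list(params.beta),
            "theta": list(params.theta),
            "lambda": params.lam,
            "sigma": params.sigma,
        },
        "mortality_config": asdict(mort_cfg),
        "engineered_tracts": engineered,
        "outcome_mode": "direct",
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
    return outdir
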