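"""End-to-end study orchestration: files in, report tables out.

The run mirrors a tract-level life-expectancy study: load mortality,
population and covariate tables; build life tables with standard errors;
screen tracts on the reliability criteria (or bypass them for a
sensitivity run on all tracts); rebuild and re-standardize the weights
matrix on the retained tracts; screen covariates for collinearity
(advisory); fit the spatial Durbin error model; decompose impacts; and
test the residuals for remaining spatial autocorrelation with Moran's I.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .diagnostics import MoranResult, VIFReport, morans_i, residual_checks, vif
from .lifetable import (
    AgeSchedule,
    ReliabilityCriteria,
    TractMortality,
    assess_reliability,
    build_default_age_schedule,
    compute_life_table,
    estimates_to_frame,
    life_expectancy_with_se,
    person_years_from_population,
    read_mortality_csv,
    read_population_csv,
)
from .sdem import ModelSpec, SDEMFit, fit_sdem, impacts
from .weights import (
    AdjacencyList,
    queen_contiguity,
    read_gal,
    read_geojson_polygons,
    row_standardize,
)

log = logging.getLogger("lifespan")

__all__ = ["StudyConfig", "StudyReport", "run_study", "write_report"]


@dataclass
class StudyConfig:
    """Inputs and options for one study run (YAML-mappable)."""

    mortality_csv: str | Path
    population_csv: str | Path
    covariates_csv: str | Path
    geometry_path: str | Path | None = None  # GeoJSON polygons
    gal_path: str | Path | None = None  # precomputed neighbors
    outcome_column: str | None = None  # use a covariate-table column as y
    study_years: int = 5
    radix: float = 100_000.0
    criteria: ReliabilityCriteria = field(default_factory=ReliabilityCriteria)
    apply_filters: bool = True
    excluded_covariates: tuple[str, ...] = ()
    include_lagged: bool = True
    drop_islands: bool = True
    vif_threshold: float = 10.0
    correlation_threshold: float = 0.7
    moran_permutations: int = 999
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "criteria" in raw and isinstance(raw["criteria"], dict):
            raw["criteria"] = ReliabilityCriteria(**raw["criteria"])
        if "excluded_covariates" in raw:
            raw["excluded_covariates"] = tuple(raw["excluded_covariates"])
        return cls(**raw)

    def config_hash(self) -> str:
        d = asdict(self)
        blob = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class StudyReport:
    le_table: pd.DataFrame
    counts: dict  # total, retained, removed, removed_by_reason, join orphans
    fit: SDEMFit
    impacts_table: pd.DataFrame | None
    vif_report: VIFReport
    moran_residuals: MoranResult
    residual_report: dict
    islands: tuple[str, ...]
    provenance: dict


def _load_adjacency(config: StudyConfig) -> AdjacencyList:
    if config.gal_path is not None:
        return read_gal(config.gal_path)
    if config.geometry_path is not None:
        return queen_contiguity(read_geojson_polygons(config.geometry_path))
    raise ValueError("either geometry_path or gal_path is required")


def run_study(
    config: StudyConfig, schedule: AgeSchedule | None = None
) -> StudyReport:
    """Execute the full pipeline; see the module docstring for the stages."""
    if schedule is None:
        schedule = build_default_age_schedule()
    k = len(schedule)

    mort = read_mortality_csv(config.mortality_csv, schedule)
    pop = read_population_csv(config.population_csv, schedule)
    cov = pd.read_csv(config.covariates_csv, dtype={"tract_id": str}).set_index(
        "tract_id"
    )
    adjacency = _load_adjacency(config)

    # inner join across all sources on tract id
    common = (
        set(mort.index) & set(pop.index) & set(cov.index) & set(adjacency.ids)
    )
    if not common:
        raise ValueError(
            "empty tract-id join; mortality ids like "
            f"{sorted(mort.index)[:3]}, adjacency ids like "
            f"{sorted(adjacency.ids)[:3]}"
        )
    orphans = {
        "mortality": len(set(mort.index) - common),
        "population": len(set(pop.index) - common),
        "covariates": len(set(cov.index) - common),
        "geometry": len(set(adjacency.ids) - common),
    }
    for src, cnt in orphans.items():
        if cnt:
            log.warning("%d %s tract(s) dropped in join", cnt, src)
    ids = sorted(common)

    # life tables and reliability screen
    estimates, verdicts = [], []
    for tid in ids:
        py = person_years_from_population(
            pop.loc[tid].to_numpy(dtype=float), config.study_years
        )
        tract = TractMortality(tid, mort.loc[tid].to_numpy(dtype=float), py)
        table = compute_life_table(tract, schedule, radix=config.radix)
        est = life_expectancy_with_se(table, tract)
        estimates.append(est)
        verdicts.append(assess_reliability(est, config.criteria))
    le_table = estimates_to_frame(estimates, verdicts)

    if config.apply_filters:
        retained_ids = [v.tract_id for v in verdicts if v.retained]
    else:
        retained_ids = list(ids)
    removed = [v for v in verdicts if v.tract_id not in set(retained_ids)]
    removed_by_reason: dict[str, int] = {}
    for v in removed:
        for r in v.reasons:
            removed_by_reason[r] = removed_by_reason.get(r, 0) + 1
    if not retained_ids:
        raise ValueError("all tracts removed by the reliability screen")

    # rebuild W on retained tracts; islands handled per policy
    sub_adj = adjacency.subset(retained_ids)
    islands = sub_adj.islands
    if islands and config.drop_islands:
        log.warning("dropping %d island tract(s): %s", len(islands), islands[:5])
        retained_ids = [t for t in retained_ids if t not in set(islands)]
        sub_adj = adjacency.subset(retained_ids)
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")  # islands already logged above
        W = row_standardize(sub_adj)

    # analysis frame in W's canonical order
    le_by_id = le_table.set_index("tract_id")
    frame = cov.loc[list(W.ids)].copy()
    covariate_names = [
        c
        for c in frame.columns
        if c not in set(config.excluded_covariates)
        and c != (config.outcome_column or "")
    ]
    if config.outcome_column:
        y = frame[config.outcome_column].to_numpy(dtype=float)
    else:
        y = le_by_id.loc[list(W.ids), "e0"].to_numpy(dtype=float)
    X = frame[covariate_names]
    n_missing = int(X.isna().any(axis=1).sum())
    if n_missing:
        keep = X.notna().all(axis=1)
        keep_ids = [t for t, k_ in zip(W.ids, keep) if k_]
        log.warning("dropping %d tract(s) with missing covariates", n_missing)
        sub_adj = sub_adj.subset(keep_ids)
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            W = row_standardize(sub_adj)
        X = X.loc[list(W.ids)]
        y = y[keep.to_numpy()]

    vif_report = vif(
        X, threshold=config.vif_threshold, pair_threshold=config.correlation_threshold
    )

    spec = ModelSpec(
        config.outcome_column or "life_expectancy",
        tuple(covariate_names),
        include_lagged=config.include_lagged,
    )
    fit = fit_sdem(y, X, W, spec)
    imp = impacts(fit).table if config.include_lagged else None

    # Moran and residual checks use the whitened innovations: the trend
    # residuals contain the modeled lambda-autocorrelation by construction
    moran = morans_i(
        fit.innovations,
        W,
        n_permutations=config.moran_permutations,
        seed=config.seed,
    )
    resid_report = residual_checks(fit.innovations, fit.fitted_trend)

    counts = {
        "total": len(ids),
        "retained": int(W.n),
        "removed": len(removed),
        "removed_by_reason": removed_by_reason,
        "removed_islands": len(islands) if config.drop_islands else 0,
        "dropped_missing_covariates": n_missing,
        "join_orphans": orphans,
    }
    provenance = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "package_version": __version__,
        "filters_applied": config.apply_filters,
    }
    return StudyReport(
        le_table=le_table,
        counts=counts,
        fit=fit,
        impacts_table=imp,
        vif_report=vif_report,
        moran_residuals=moran,
        residual_report=resid_report,
        islands=islands,
        provenance=provenance,
    )


def _coefficients_frame(fit: SDEMFit) -> pd.DataFrame:
    """Coefficient table shaped like the usual two-column report:
    indicator, direct estimate (with stars), lagged estimate (with stars)."""
    rows = [
        {
            "indicator": "intercept",
            "sdem_model": f"{fit.alpha:.4g}",
            "sdem_lag": "NA",
        }
    ]
    for name in fit.spec.covariate_names:
        direct = fit.params.loc[name]
        row = {
            "indicator": name,
            "sdem_model": f"{direct['estimate']:.4g}{direct['stars']}",
        }
        if fit.spec.include_lagged:
            lagged = fit.params.loc[f"lag_{name}"]
            row["sdem_lag"] = f"{lagged['estimate']:.4g}{lagged['stars']}"
        else:
            row["sdem_lag"] = "NA"
        rows.append(row)
    return pd.DataFrame(rows)


def write_report(report: StudyReport, outdir: str | Path) -> dict[str, Path]:
    """Write LE CSV, coefficient CSV, diagnostics JSON and a run log."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    paths["life_expectancy"] = outdir / "life_expectancy.csv"
    report.le_table.to_csv(paths["life_expectancy"], index=False)

    paths["coefficients"] = outdir / "coefficients.csv"
    _coefficients_frame(report.fit).to_csv(paths["coefficients"], index=False)

    if report.impacts_table is not None:
        paths["impacts"] = outdir / "impacts.csv"
        report.impacts_table.to_csv(paths["impacts"])

    diag = {
        "model": report.fit.to_json_dict(),
        "vif": report.vif_report.to_json_dict(),
        "moran_residuals": report.moran_residuals.to_json_dict(),
        "residual_checks": report.residual_report,
        "counts": report.counts,
        "islands": list(report.islands),
        "provenance": report.provenance,
    }
    paths["diagnostics"] = outdir / "diagnostics.json"
    with open(paths["diagnostics"], "w") as fh:
        json.dump(diag, fh, indent=2, sort_keys=True)

    paths["run_log"] = outdir / "run_log.txt"
    with open(paths["run_log"], "w") as fh:
        fh.write(
            f"lifespan {__version__}\n"
            f"config hash: {report.provenance['config_hash']}\n"
            f"tracts: {report.counts['total']} total, "
            f"{report.counts['retained']} retained, "
            f"{report.counts['removed']} removed "
            f"{report.counts['removed_by_reason']}\n"
            f"lambda: {report.fit.lam:.6f}  loglik: {report.fit.loglik:.4f}  "
            f"AIC: {report.fit.aic:.4f}  R2: {report.fit.r_squared:.4f}\n"
            f"Moran's I on residuals: {report.moran_residuals.I:.6f} "
            f"(p={report.moran_residuals.p_value:.4f})\n"
        )
    return paths
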