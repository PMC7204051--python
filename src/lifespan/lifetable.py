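"""Abridged life tables by the adjusted Chiang II method.

Builds the 19-interval abridged age schedule used in small-area life
expectancy work (<1, 1-4, sixteen 5-year bins, 85+), converts age-grouped
deaths and person-years into a full life table, attaches the Chiang-style
standard error of life expectancy at birth, and applies the reliability
screen used to drop tracts with unstable estimates.

Notation follows the standard abridged life-table columns: for interval i
with width ``n_i`` and fraction-of-interval-lived ``a_i``,

    m_i = D_i / PY_i                              (central death rate)
    q_i = n_i m_i / (1 + n_i (1 - a_i) m_i)       (probability of dying)

with q = 1 in the open-ended final interval and L_open = l_open / m_open.
The variance of e0 aggregates per-interval binomial variances of q_i,

    Var(q_i) = q_i^2 (1 - q_i) / D_i,

weighted by l_i^2 [(1 - a_i) n_i + e_{i+1}]^2, plus a final-interval term
(l_open / l_0)^2 / (m_open^2 D_open) accounting for sampling error in the
open-interval rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AgeInterval",
    "AgeSchedule",
    "TractMortality",
    "LifeTable",
    "LifeExpectancyEstimate",
    "ReliabilityCriteria",
    "ReliabilityVerdict",
    "build_default_age_schedule",
    "person_years_from_population",
    "compute_life_table",
    "life_expectancy_with_se",
    "assess_reliability",
    "read_mortality_csv",
    "read_population_csv",
    "estimates_to_frame",
]

DEFAULT_RADIX = 100_000.0


@dataclass(frozen=True)
class AgeInterval:
    """One abridged age interval.

    ``width`` is None for the open-ended final interval.  ``a_fraction``
    is the average fraction of the interval lived by those who die in it
    (Chiang's a_i); 0.5 encodes deaths spread evenly through the interval.
    """

    start_age: int
    width: int | None
    a_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.start_age < 0:
            raise ValueError("start_age must be >= 0")
        if self.width is not None and self.width <= 0:
            raise ValueError("width must be positive (or None for open-ended)")
        if not 0.0 <= self.a_fraction <= 1.0:
            raise ValueError("a_fraction must lie in [0, 1]")

    @property
    def is_open(self) -> bool:
        return self.width is None

    @property
    def label(self) -> str:
        if self.is_open:
            return f"{self.start_age}+"
        if self.width == 1:
            return f"<{self.start_age + 1}"
        return f"{self.start_age}-{self.start_age + self.width - 1}"


@dataclass(frozen=True)
class AgeSchedule:
    """Ordered, contiguous abridged age intervals; exactly one open-ended, last."""

    intervals: tuple[AgeInterval, ...]

    def __post_init__(self) -> None:
        if not self.intervals:
            raise ValueError("schedule must contain at least one interval")
        if self.intervals[0].start_age != 0:
            raise ValueError("first interval must start at age 0")
        for prev, cur in zip(self.intervals, self.intervals[1:]):
            if prev.is_open:
                raise ValueError("only the final interval may be open-ended")
            if prev.start_age + prev.width != cur.start_age:
                raise ValueError("intervals must be contiguous and non-overlapping")
        if not self.intervals[-1].is_open:
            raise ValueError("the final interval must be open-ended")

    def __len__(self) -> int:
        return len(self.intervals)

    @property
    def widths(self) -> np.ndarray:
        """Closed-interval widths; the open interval contributes NaN."""
        return np.array(
            [np.nan if iv.is_open else float(iv.width) for iv in self.intervals]
        )

    @property
    def a_fractions(self) -> np.ndarray:
        return np.array([iv.a_fraction for iv in self.intervals])

    @property
    def labels(self) -> list[str]:
        return [iv.label for iv in self.intervals]


def build_default_age_schedule(
    a_fraction: float = 0.5, infant_a: float | None = None
) -> AgeSchedule:
    """The 19-interval abridged schedule: <1, 1-4, 5-9, ..., 80-84, 85+.

    ``a_fraction`` applies to every interval (default 0.5: deaths spread
    evenly within intervals).  ``infant_a`` optionally overrides the <1
    interval, where deaths concentrate early in life (e.g. 0.1).
    """
    a0 = a_fraction if infant_a is None else infant_a
    intervals = [AgeInterval(0, 1, a0), AgeInterval(1, 4, a_fraction)]
    intervals += [AgeInterval(5 + 5 * j, 5, a_fraction) for j in range(16)]
    intervals.append(AgeInterval(85, None, a_fraction))
    return AgeSchedule(tuple(intervals))


@dataclass(frozen=True)
class TractMortality:
    """Deaths and person-years of exposure per age interval for one tract."""

    tract_id: str
    deaths: np.ndarray
    person_years: np.ndarray

    def __post_init__(self) -> None:
        deaths = np.asarray(self.deaths, dtype=float)
        py = np.asarray(self.person_years, dtype=float)
        if deaths.shape != py.shape or deaths.ndim != 1:
            raise ValueError("deaths and person_years must be 1-D and equal length")
        if not (np.all(np.isfinite(deaths)) and np.all(np.isfinite(py))):
            raise ValueError("deaths and person_years must be finite")
        if np.any(deaths < 0) or np.any(py < 0):
            raise ValueError("deaths and person_years must be non-negative")
        object.__setattr__(self, "deaths", deaths)
        object.__setattr__(self, "person_years", py)

    @property
    def total_deaths(self) -> float:
        return float(self.deaths.sum())

    @property
    def total_person_years(self) -> float:
        return float(self.person_years.sum())


def person_years_from_population(
    population_by_age: np.ndarray, study_years: int
) -> np.ndarray:
    """Person-years of exposure: census population per age group x study length."""
    pop = np.asarray(population_by_age, dtype=float)
    if np.any(pop < 0):
        raise ValueError("population counts must be non-negative")
    if study_years < 1:
        raise ValueError("study_years must be >= 1")
    return pop * float(study_years)


@dataclass
class LifeTable:
    """Full abridged life-table columns for one tract."""

    schedule: AgeSchedule
    m: np.ndarray
    q: np.ndarray
    l: np.ndarray
    d_lt: np.ndarray
    L: np.ndarray
    T: np.ndarray
    e: np.ndarray
    radix: float = DEFAULT_RADIX

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "age_group": self.schedule.labels,
                "m": self.m,
                "q": self.q,
                "l": self.l,
                "d": self.d_lt,
                "L": self.L,
                "T": self.T,
                "e": self.e,
            }
        )


class InfiniteRateError(ValueError):
    """Deaths observed in an interval with zero person-years of exposure."""


class DegenerateTailError(ValueError):
    """Survivors reach the open interval but its death rate is zero."""


def compute_life_table(
    tract: TractMortality,
    schedule: AgeSchedule | None = None,
    radix: float = DEFAULT_RADIX,
) -> LifeTable:
    """Adjusted Chiang II abridged life table from deaths and person-years.

    Zero deaths in a stratum produce q = 0 and survival passes through
    unchanged.  An empty stratum (0 deaths and 0 person-years) is treated
    as rate 0, never NaN.  Extreme rates that push the closed-interval q
    above 1 are clamped to 1, zeroing survival thereafter.
    """
    if schedule is None:
        schedule = build_default_age_schedule()
    k = len(schedule)
    D = tract.deaths
    PY = tract.person_years
    if D.shape[0] != k:
        raise ValueError(
            f"tract {tract.tract_id}: {D.shape[0]} intervals, schedule has {k}"
        )
    a = schedule.a_fractions
    n = schedule.widths  # NaN in the open slot

    m = np.zeros(k)
    for i in range(k):
        if PY[i] > 0:
            m[i] = D[i] / PY[i]
        elif D[i] > 0:
            raise InfiniteRateError(
                f"tract {tract.tract_id}: deaths with zero exposure in "
                f"interval {schedule.intervals[i].label}"
            )
        # else: empty stratum, m stays 0

    q = np.empty(k)
    closed = slice(0, k - 1)
    q[closed] = (n[closed] * m[closed]) / (
        1.0 + n[closed] * (1.0 - a[closed]) * m[closed]
    )
    np.clip(q[closed], 0.0, 1.0, out=q[closed])
    q[-1] = 1.0

    l = np.empty(k)
    l[0] = radix
    for i in range(k - 1):
        l[i + 1] = l[i] * (1.0 - q[i])
    d_lt = l * q  # final interval: everyone remaining dies

    L = np.empty(k)
    L[closed] = n[closed] * (l[1:] + a[closed] * d_lt[closed])
    if l[-1] > 0:
        if m[-1] <= 0:
            raise DegenerateTailError(
                f"tract {tract.tract_id}: survivors at age "
                f"{schedule.intervals[-1].start_age}+ but zero open-interval rate"
            )
        L[-1] = l[-1] / m[-1]
    else:
        L[-1] = 0.0

    T = np.cumsum(L[::-1])[::-1]
    with np.errstate(invalid="ignore", divide="ignore"):
        e = np.where(l > 0, T / np.where(l > 0, l, 1.0), 0.0)
    return LifeTable(schedule, m, q, l, d_lt, L, T, e, radix)


@dataclass(frozen=True)
class LifeExpectancyEstimate:
    tract_id: str
    e0: float
    se: float
    ci_low: float
    ci_high: float
    total_deaths: float
    total_person_years: float


def life_expectancy_with_se(
    table: LifeTable, tract: TractMortality, z: float = 1.96
) -> LifeExpectancyEstimate:
    """e0 with its Chiang-style standard error and normal confidence interval.

    Closed intervals contribute l_i^2 [(1-a_i) n_i + e_{i+1}]^2 Var(q_i)
    with Var(q_i) = q_i^2 (1-q_i)/D_i (zero when D_i = 0); the open
    interval contributes (l_open/l_0)^2 / (m_open^2 D_open) when deaths
    were observed there.
    """
    k = len(table.schedule)
    D = tract.deaths
    a = table.schedule.a_fractions
    n = table.schedule.widths
    q, l, m, e = table.q, table.l, table.m, table.e
    radix = table.radix

    var = 0.0
    for i in range(k - 1):
        if D[i] > 0:
            var_q = q[i] ** 2 * (1.0 - q[i]) / D[i]
            weight = l[i] * ((1.0 - a[i]) * n[i] + e[i + 1])
            var += weight**2 * var_q
    var /= radix**2
    if D[-1] > 0 and m[-1] > 0:
        var += (l[-1] / radix) ** 2 / (m[-1] ** 2 * D[-1])

    se = math.sqrt(var)
    e0 = float(e[0])
    return LifeExpectancyEstimate(
        tract_id=tract.tract_id,
        e0=e0,
        se=se,
        ci_low=e0 - z * se,
        ci_high=e0 + z * se,
        total_deaths=tract.total_deaths,
        total_person_years=tract.total_person_years,
    )


@dataclass(frozen=True)
class ReliabilityCriteria:
    """Screen for unstable tract estimates; boundaries are strict as printed:
    fewer than 50 deaths, fewer than 5000 person-years, SE above 2 years."""

    min_deaths: float = 50.0
    min_person_years: float = 5000.0
    max_se: float = 2.0

    def __post_init__(self) -> None:
        if min(self.min_deaths, self.min_person_years, self.max_se) <= 0:
            raise ValueError("all reliability thresholds must be positive")


@dataclass(frozen=True)
class ReliabilityVerdict:
    tract_id: str
    retained: bool
    reasons: tuple[str, ...] = field(default=())


def assess_reliability(
    est: LifeExpectancyEstimate, criteria: ReliabilityCriteria | None = None
) -> ReliabilityVerdict:
    """Apply the a/b/c screen: deaths, person-years, standard error."""
    if criteria is None:
        criteria = ReliabilityCriteria()
    reasons = []
    if est.total_deaths < criteria.min_deaths:
        reasons.append("deaths")
    if est.total_person_years < criteria.min_person_years:
        reasons.append("person_years")
    if est.se > criteria.max_se:
        reasons.append("se")
    return ReliabilityVerdict(est.tract_id, retained=not reasons, reasons=tuple(reasons))


# ---------------------------------------------------------------------------
# CSV interfaces


def _read_wide_csv(path, prefix: str, k: int) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"tract_id": str})
    cols = [f"{prefix}_{i:02d}" for i in range(k)]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df.set_index("tract_id")[cols]


def read_mortality_csv(path, schedule: AgeSchedule | None = None) -> pd.DataFrame:
    """Deaths table: one row per tract, columns d_00..d_18 in schedule order."""
    k = len(schedule) if schedule else 19
    return _read_wide_csv(path, "d", k)


def read_population_csv(path, schedule: AgeSchedule | None = None) -> pd.DataFrame:
    """Population table: one row per tract, columns p_00..p_18."""
    k = len(schedule) if schedule else 19
    return _read_wide_csv(path, "p", k)


def estimates_to_frame(
    estimates: list[LifeExpectancyEstimate], verdicts: list[ReliabilityVerdict]
) -> pd.DataFrame:
    """Combined estimate/verdict table in the output CSV layout."""
    by_id = {v.tract_id: v for v in verdicts}
    rows = []
    for est in estimates:
        v = by_id[est.tract_id]
        rows.append(
            {
                "tract_id": est.tract_id,
                "e0": est.e0,
                "se": est.se,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "total_deaths": est.total_deaths,
                "total_person_years": est.total_person_years,
                "retained": v.retained,
                "reasons": ";".join(v.reasons),
            }
        )
    return pd.DataFrame(rows)
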