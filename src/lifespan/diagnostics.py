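"""Model diagnostics: collinearity screening, Moran's I, residual checks.

VIF_k = 1/(1 - R^2_k) from regressing covariate k on the remaining
covariates plus an intercept; values above 10 (or a pairwise Pearson
|r| > 0.7) flag candidates for exclusion.  Flags are advisory — the
analyst chooses which of a correlated pair to keep.

Global Moran's I on a mean-centered vector e:

    I = (n / S0) * (e' W e) / (e' e),     S0 = sum_ij w_ij,

with expectation -1/(n-1) under the null of no spatial autocorrelation.
The default test is a two-sided permutation test (values randomly
reassigned to tracts); a normal approximation under randomization is
available as an alternative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .weights import SpatialWeights

__all__ = [
    "VIFReport",
    "MoranResult",
    "vif",
    "morans_i",
    "residual_checks",
]


@dataclass
class VIFReport:
    vif: pd.Series  # per covariate
    flagged: pd.Series  # vif > threshold
    threshold: float
    correlation_pairs: list[tuple[str, str, float]]  # |r| > pair threshold
    pair_threshold: float

    def to_json_dict(self) -> dict:
        return {
            "vif": {k: float(v) for k, v in self.vif.items()},
            "flagged": [k for k, f in self.flagged.items() if f],
            "threshold": self.threshold,
            "correlation_pairs": [
                {"a": a, "b": b, "r": float(r)} for a, b, r in self.correlation_pairs
            ],
            "pair_threshold": self.pair_threshold,
        }


def vif(
    X: pd.DataFrame, threshold: float = 10.0, pair_threshold: float = 0.7
) -> VIFReport:
    """Variance inflation factors and high-correlation pairs for a covariate table."""
    Xm = X.to_numpy(dtype=float)
    n, p = Xm.shape
    if n <= p + 1:
        raise ValueError(f"need more than p+1={p + 1} rows, have {n}")
    sd = Xm.std(axis=0)
    for j in range(p):
        if sd[j] == 0:
            raise ValueError(f"constant covariate column: {X.columns[j]}")

    vifs = np.empty(p)
    ones = np.ones((n, 1))
    for j in range(p):
        yj = Xm[:, j]
        others = np.hstack([ones, np.delete(Xm, j, axis=1)])
        coef, _, _, _ = np.linalg.lstsq(others, yj, rcond=None)
        resid = yj - others @ coef
        tss = float(((yj - yj.mean()) ** 2).sum())
        r2 = 1.0 - float(resid @ resid) / tss
        r2 = min(r2, 1.0 - 1e-15)
        vifs[j] = 1.0 / (1.0 - r2)

    corr = np.corrcoef(Xm, rowvar=False)
    pairs = [
        (str(X.columns[i]), str(X.columns[j]), float(corr[i, j]))
        for i in range(p)
        for j in range(i + 1, p)
        if abs(corr[i, j]) > pair_threshold
    ]
    vser = pd.Series(vifs, index=X.columns, name="vif")
    return VIFReport(
        vif=vser,
        flagged=vser > threshold,
        threshold=threshold,
        correlation_pairs=pairs,
        pair_threshold=pair_threshold,
    )


@dataclass
class MoranResult:
    I: float
    expected_I: float
    p_value: float
    n_permutations: int
    method: str  # "permutation" or "normal-approximation"
    z_score: float | None = None

    def to_json_dict(self) -> dict:
        return {
            "I": self.I,
            "expected_I": self.expected_I,
            "p_value": self.p_value,
            "n_permutations": self.n_permutations,
            "method": self.method,
            "z_score": self.z_score,
        }


def _moran_stat(e: np.ndarray, W: SpatialWeights, s0: float) -> float:
    n = e.shape[0]
    return float(n / s0 * (e @ (W.weights @ e)) / (e @ e))


def morans_i(
    values: np.ndarray,
    W: SpatialWeights,
    n_permutations: int = 999,
    seed: int | np.random.Generator | None = 0,
    method: str = "permutation",
) -> MoranResult:
    """Global Moran's I with a two-sided permutation (or normal) p-value.

    The permutation p-value is (#{|I_perm - E[I]| >= |I_obs - E[I]|} + 1)
    / (n_permutations + 1), under random reassignment of values to tracts.
    """
    x = np.asarray(values, dtype=float)
    if x.shape[0] != W.n:
        raise ValueError("values must align with the weights matrix")
    if np.ptp(x) == 0:
        raise ValueError("Moran's I undefined for constant input (zero variance)")
    n = x.shape[0]
    e = x - x.mean()
    s0 = float(W.weights.sum())
    i_obs = _moran_stat(e, W, s0)
    e_i = -1.0 / (n - 1)

    if method == "permutation":
        rng = (
            seed
            if isinstance(seed, np.random.Generator)
            else np.random.default_rng(seed)
        )
        # W e for every permutation at once via the COO triplets
        coo = W.weights.tocoo()
        perms = np.empty((n_permutations, n))
        for b in range(n_permutations):
            perms[b] = rng.permutation(e)
        quad = np.einsum(
            "bi,bi->b", perms[:, coo.row] * coo.data, perms[:, coo.col]
        )
        i_perm = n / s0 * quad / float(e @ e)
        exceed = int(np.sum(np.abs(i_perm - e_i) >= np.abs(i_obs - e_i) - 1e-14))
        p = (exceed + 1) / (n_permutations + 1)
        return MoranResult(i_obs, e_i, float(p), n_permutations, "permutation")

    if method == "normal-approximation":
        # moments under randomization
        Wd = W.weights.toarray()
        s1 = 0.5 * float(((Wd + Wd.T) ** 2).sum())
        rs = Wd.sum(axis=1)
        cs = Wd.sum(axis=0)
        s2 = float(((rs + cs) ** 2).sum())
        b2 = n * float((e**4).sum()) / float((e**2).sum()) ** 2
        num = n * ((n**2 - 3 * n + 3) * s1 - n * s2 + 3 * s0**2) - b2 * (
            (n**2 - n) * s1 - 2 * n * s2 + 6 * s0**2
        )
        den = (n - 1) * (n - 2) * (n - 3) * s0**2
        var_i = num / den - e_i**2
        z = (i_obs - e_i) / np.sqrt(var_i)
        p = float(2 * stats.norm.sf(abs(z)))
        return MoranResult(i_obs, e_i, p, 0, "normal-approximation", z_score=float(z))

    raise ValueError(f"unknown method {method!r}")


def residual_checks(residuals: np.ndarray, fitted: np.ndarray) -> dict:
    """Advisory residual diagnostics: normality and heteroscedasticity.

    Normality via the skewness/kurtosis omnibus test; heteroscedasticity
    via the slope of squared residuals on fitted values.  Never raises on
    bad residuals — a degenerate (constant) residual vector is flagged
    and the tests are skipped.
    """
    r = np.asarray(residuals, dtype=float)
    f = np.asarray(fitted, dtype=float)
    if not np.all(np.isfinite(r)):
        raise ValueError("residuals must be finite")
    if np.ptp(r) == 0:
        return {"degenerate": True, "normality": None, "heteroscedasticity": None}

    k2, norm_p = stats.normaltest(r)
    out = {
        "degenerate": False,
        "normality": {"statistic": float(k2), "p": float(norm_p)},
    }
    if np.ptp(f) == 0:
        out["heteroscedasticity"] = None
        return out
    slope_fit = stats.linregress(f, r**2)
    out["heteroscedasticity"] = {
        "slope": float(slope_fit.slope),
        "p": float(slope_fit.pvalue),
    }
    return out
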