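"""Spatial Durbin error model (SDEM) by concentrated maximum likelihood.

The model regresses a tract-level outcome y (here life expectancy at
birth) on local covariates X and their spatial lags WX, with a spatially
autocorrelated error:

    y = alpha + X beta + W X theta + u,      u = lambda W u + eps,
    eps ~ N(0, sigma^2 I).

With A = I - lambda W the log-likelihood concentrates over the regression
coefficients gamma = (alpha, beta, theta) and sigma^2: for fixed lambda,
gamma_hat(lambda) solves the least-squares problem of Ay on AZ (Z the
design [1 | X | WX]), sigma2_hat = RSS/n, and

    ell(lambda) = -(n/2)(ln 2pi + 1 + ln sigma2_hat) + ln|A|,

where ln|A| = sum_i ln(1 - lambda omega_i) over the eigenvalues of the
row-standardized W.  lambda is found by bounded scalar optimization over
(1/omega_min, 1).

Direct effects are the beta coefficients, indirect (neighbor) effects the
theta coefficients, and total effects their sum; only direct and indirect
effects carry significance.  Because the spatial structure sits in the
error term, these local-spillover effects read off the coefficients
directly — no global multiplier inversion is involved.

`SpatialDurbinError` is a scikit-learn estimator (``fit``/``predict``/
``get_params``) so it composes with sklearn model-selection tooling; the
module-level functions `fit_sdem`, `impacts` and `lr_test` are thin
wrappers over it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .weights import SpatialWeights, spatial_lag

__all__ = [
    "ModelSpec",
    "SDEMFit",
    "ImpactsTable",
    "SpatialDurbinError",
    "build_design",
    "log_jacobian",
    "profile_loglik",
    "fit_sdem",
    "impacts",
    "lr_test",
    "significance_stars",
]

_LAMBDA_MARGIN = 1e-6


@dataclass(frozen=True)
class ModelSpec:
    """Names the outcome and covariates; include_lagged adds the WX block."""

    outcome_name: str
    covariate_names: tuple[str, ...]
    include_lagged: bool = True

    def __post_init__(self) -> None:
        names = tuple(self.covariate_names)
        if not names:
            raise ValueError("at least one covariate is required")
        if len(set(names)) != len(names):
            raise ValueError("covariate names must be unique")
        object.__setattr__(self, "covariate_names", names)


def significance_stars(p: float) -> str:
    """Star convention: * p<=0.05, ** p<=0.01, *** p<=0.001."""
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return ""


def build_design(
    X: pd.DataFrame, W: SpatialWeights, spec: ModelSpec
) -> tuple[np.ndarray, list[str], list[str]]:
    """Design Z = [1 | X | WX], with column labels and block labels.

    X rows must already be aligned to W's canonical id order; lag columns
    are labeled ``lag_<name>``.
    """
    Xm = X[list(spec.covariate_names)].to_numpy(dtype=float)
    bad = ~np.isfinite(Xm)
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ValueError(
            f"non-finite covariate value: column {spec.covariate_names[c]}, "
            f"tract {W.ids[r]}"
        )
    cols = [np.ones(Xm.shape[0])]
    labels = ["intercept"]
    blocks = ["intercept"]
    for j, name in enumerate(spec.covariate_names):
        cols.append(Xm[:, j])
        labels.append(name)
        blocks.append("direct")
    if spec.include_lagged:
        for j, name in enumerate(spec.covariate_names):
            cols.append(spatial_lag(W, Xm[:, j]))
            labels.append(f"lag_{name}")
            blocks.append("lag")
    return np.column_stack(cols), labels, blocks


def log_jacobian(lam: float, eigenvalues: np.ndarray) -> float:
    """ln|I - lambda W| from the spectrum of W."""
    terms = 1.0 - lam * np.asarray(eigenvalues, dtype=float)
    if np.any(terms <= 0):
        raise ValueError(f"lambda={lam} outside the admissible interval")
    return float(np.sum(np.log(terms)))


def _concentrated(lam, y, Z, Wy, WZ, eigenvalues):
    """gamma_hat, RSS and the profile log-likelihood at one lambda."""
    n = y.shape[0]
    Ay = y - lam * Wy
    AZ = Z - lam * WZ
    gamma, _, rank, _ = np.linalg.lstsq(AZ, Ay, rcond=None)
    if rank < Z.shape[1]:
        raise np.linalg.LinAlgError(
            f"design is rank deficient (rank {rank} < {Z.shape[1]} columns); "
            "check for collinear or constant covariates"
        )
    resid = Ay - AZ @ gamma
    rss = float(resid @ resid)
    if rss <= 1e-10 * max(1.0, float(Ay @ Ay)):
        return gamma, 0.0, np.inf  # perfect-fit guard: sigma2 -> 0 limit
    sigma2 = rss / n
    ll = -0.5 * n * (np.log(2 * np.pi) + 1.0 + np.log(sigma2)) + log_jacobian(
        lam, eigenvalues
    )
    return gamma, rss, ll


def profile_loglik(
    lam: float, y: np.ndarray, Z: np.ndarray, W: SpatialWeights
) -> float:
    """Concentrated log-likelihood of the spatial-error regression at lambda."""
    y = np.asarray(y, dtype=float)
    Wy = W.weights @ y
    WZ = W.weights @ Z
    return _concentrated(lam, y, Z, Wy, WZ, W.eigenvalues)[2]


@dataclass
class SDEMFit:
    """Fitted SDEM: coefficient table plus likelihood summaries."""

    params: pd.DataFrame  # index: labels; columns: block, estimate, se, z, p, stars
    lam: float
    lam_se: float
    sigma2: float
    loglik: float
    aic: float
    r_squared: float
    n: int
    k: int
    spec: ModelSpec
    converged: bool
    fitted_trend: np.ndarray
    residuals: np.ndarray  # trend residuals u_hat = y - Z gamma_hat
    innovations: np.ndarray  # whitened: (I - lambda_hat W) u_hat

    @property
    def alpha(self) -> float:
        return float(self.params.loc["intercept", "estimate"])

    @property
    def beta(self) -> pd.Series:
        return self.params.loc[self.params["block"] == "direct", "estimate"]

    @property
    def theta(self) -> pd.Series:
        return self.params.loc[self.params["block"] == "lag", "estimate"]

    def to_json_dict(self) -> dict:
        return {
            "coefficients": [
                {
                    "name": name,
                    "block": row["block"],
                    "estimate": row["estimate"],
                    "se": row["se"],
                    "z": row["z"],
                    "p": row["p"],
                    "stars": row["stars"],
                }
                for name, row in self.params.iterrows()
            ],
            "lambda": self.lam,
            "lambda_se": self.lam_se,
            "sigma2": self.sigma2,
            "loglik": self.loglik,
            "aic": self.aic,
            "r_squared": self.r_squared,
            "r_squared_definition": "squared Pearson correlation of observed outcome with the trend prediction Z gamma_hat",
            "n": self.n,
            "k": self.k,
        }


class SpatialDurbinError(RegressorMixin, BaseEstimator):
    """Spatial Durbin error regression with concentrated-ML estimation.

    Parameters
    ----------
    weights : SpatialWeights
        Row-standardized queen-contiguity (or other) weights; rows of X/y
        must follow its canonical tract order.  Island-free graphs are
        assumed; drop islands upstream.
    include_lagged : bool, default True
        Include the WX block (the Durbin part).  False gives the plain
        spatial-error model (SEM).
    fix_lambda : float or None, default None
        Fix the error autocorrelation instead of estimating it (0 gives
        OLS-equivalent coefficients); its SE is then 0.
    optimizer_tol : float, default 1e-8
        Absolute tolerance of the bounded 1-D search for lambda.

    Attributes (after ``fit``)
    ----------
    coef_ : ndarray of the full coefficient vector gamma (intercept, beta, theta)
    lambda_ : estimated error autocorrelation
    sigma2_ : residual variance
    loglik_, aic_, r_squared_ : fit summaries
    results_ : SDEMFit with the labeled coefficient table
    """

    def __init__(
        self,
        weights: SpatialWeights = None,
        include_lagged: bool = True,
        fix_lambda: float | None = None,
        optimizer_tol: float = 1e-8,
    ):
        self.weights = weights
        self.include_lagged = include_lagged
        self.fix_lambda = fix_lambda
        self.optimizer_tol = optimizer_tol

    # -- estimation -------------------------------------------------------

    def fit(self, X, y, covariate_names=None, outcome_name="life_expectancy"):
        if self.weights is None:
            raise ValueError("a SpatialWeights instance is required")
        W = self.weights
        if isinstance(X, pd.DataFrame):
            names = tuple(covariate_names or X.columns)
            Xdf = X
        else:
            X = np.asarray(X, dtype=float)
            names = tuple(
                covariate_names or [f"x{j}" for j in range(X.shape[1])]
            )
            Xdf = pd.DataFrame(X, columns=list(names))
        y = np.asarray(y, dtype=float).ravel()
        if Xdf.shape[0] != W.n or y.shape[0] != W.n:
            raise ValueError(
                f"X ({Xdf.shape[0]}) and y ({y.shape[0]}) must match the "
                f"{W.n} tracts of the weights matrix"
            )
        spec = ModelSpec(outcome_name, names, include_lagged=self.include_lagged)
        Z, labels, blocks = build_design(Xdf, W, spec)
        n, k = Z.shape
        if n < k + 2:
            raise ValueError(f"need at least k+2={k + 2} tracts, have {n}")

        Wy = W.weights @ y
        WZ = W.weights @ Z
        ev = W.eigenvalues
        lo = 1.0 / ev.min() + _LAMBDA_MARGIN
        hi = 1.0 - _LAMBDA_MARGIN

        converged = True
        if self.fix_lambda is not None:
            lam = float(self.fix_lambda)
            lam_se = 0.0
        else:
            res = optimize.minimize_scalar(
                lambda lam: -_concentrated(lam, y, Z, Wy, WZ, ev)[2],
                bounds=(lo, hi),
                method="bounded",
                options={"xatol": self.optimizer_tol},
            )
            lam = float(res.x)
            boundary_tol = 50 * _LAMBDA_MARGIN
            if lam <= lo + boundary_tol or lam >= hi - boundary_tol:
                converged = False
            # SE from the numerical curvature of the profile likelihood
            h = 1e-5 * max(1.0, abs(lam))
            h = min(h, (hi - lam) / 2, (lam - lo) / 2) or 1e-8
            ll0 = _concentrated(lam, y, Z, Wy, WZ, ev)[2]
            llp = _concentrated(lam + h, y, Z, Wy, WZ, ev)[2]
            llm = _concentrated(lam - h, y, Z, Wy, WZ, ev)[2]
            d2 = (llp - 2 * ll0 + llm) / h**2
            lam_se = float(np.sqrt(-1.0 / d2)) if d2 < 0 else np.nan

        gamma, rss, ll = _concentrated(lam, y, Z, Wy, WZ, ev)
        sigma2 = rss / n
        AZ = Z - lam * WZ
        if sigma2 > 0:
            cov = sigma2 * np.linalg.inv(AZ.T @ AZ)
            se = np.sqrt(np.diag(cov))
        else:
            se = np.zeros(k)
        with np.errstate(divide="ignore", invalid="ignore"):
            zval = np.where(se > 0, gamma / se, np.inf * np.sign(gamma))
        pval = 2.0 * stats.norm.sf(np.abs(zval))

        trend = Z @ gamma
        if np.std(trend) > 0 and np.std(y) > 0:
            r2 = float(np.corrcoef(y, trend)[0, 1] ** 2)
        else:
            r2 = np.nan
        aic = 2.0 * (k + 2) - 2.0 * ll

        params = pd.DataFrame(
            {
                "block": blocks,
                "estimate": gamma,
                "se": se,
                "z": zval,
                "p": pval,
                "stars": [significance_stars(p) for p in pval],
            },
            index=pd.Index(labels, name="name"),
        )
        self.results_ = SDEMFit(
            params=params,
            lam=lam,
            lam_se=lam_se,
            sigma2=sigma2,
            loglik=float(ll),
            aic=float(aic),
            r_squared=r2,
            n=n,
            k=k,
            spec=spec,
            converged=converged,
            fitted_trend=trend,
            residuals=y - trend,
            innovations=(y - trend) - lam * (W.weights @ (y - trend)),
        )
        self.coef_ = gamma
        self.feature_names_in_ = np.array(labels)
        self.lambda_ = lam
        self.sigma2_ = sigma2
        self.loglik_ = float(ll)
        self.aic_ = float(aic)
        self.r_squared_ = r2
        self.n_features_in_ = Xdf.shape[1]
        return self

    def predict(self, X):
        """Trend prediction Z gamma_hat on the fitted tract set.

        X must be aligned to the fitted weights matrix (spatial lags of
        the covariates are taken with it).
        """
        check_is_fitted(self, "results_")
        Xdf = X if isinstance(X, pd.DataFrame) else pd.DataFrame(
            np.asarray(X, dtype=float), columns=list(self.results_.spec.covariate_names)
        )
        Z, _, _ = build_design(Xdf, self.weights, self.results_.spec)
        return Z @ self.coef_


# ---------------------------------------------------------------------------
# Functional wrappers


def fit_sdem(
    y,
    X: pd.DataFrame,
    W: SpatialWeights,
    spec: ModelSpec | None = None,
    fix_lambda: float | None = None,
) -> SDEMFit:
    """Fit the SDEM (or SEM when the spec excludes the lag block)."""
    if spec is None:
        spec = ModelSpec("life_expectancy", tuple(X.columns))
    est = SpatialDurbinError(
        weights=W, include_lagged=spec.include_lagged, fix_lambda=fix_lambda
    )
    est.fit(
        X[list(spec.covariate_names)],
        y,
        covariate_names=spec.covariate_names,
        outcome_name=spec.outcome_name,
    )
    return est.results_


@dataclass
class ImpactsTable:
    """Direct (beta), indirect (theta) and total (beta+theta) effects.

    Totals carry no significance measure: the model reports p-values for
    the local and neighbor coefficients only.
    """

    table: pd.DataFrame


def impacts(fit: SDEMFit) -> ImpactsTable:
    if not fit.spec.include_lagged:
        raise ValueError("impacts require a fit with the lagged-X block")
    rows = []
    for name in fit.spec.covariate_names:
        direct = fit.params.loc[name]
        indirect = fit.params.loc[f"lag_{name}"]
        rows.append(
            {
                "covariate": name,
                "direct": direct["estimate"],
                "direct_p": direct["p"],
                "direct_stars": direct["stars"],
                "indirect": indirect["estimate"],
                "indirect_p": indirect["p"],
                "indirect_stars": indirect["stars"],
                "total": direct["estimate"] + indirect["estimate"],
            }
        )
    return ImpactsTable(pd.DataFrame(rows).set_index("covariate"))


def lr_test(fit_full: SDEMFit, fit_nested: SDEMFit) -> tuple[float, int, float]:
    """Likelihood-ratio test of a nested spatial-error specification.

    Returns (statistic, df, p).  The nested model's regression columns
    must be a subset of the full model's, on the same data.
    """
    full_labels = set(fit_full.params.index)
    nested_labels = set(fit_nested.params.index)
    if not nested_labels < full_labels or fit_full.n != fit_nested.n:
        raise ValueError("models are not nested on the same data")
    stat = max(0.0, 2.0 * (fit_full.loglik - fit_nested.loglik))
    df = fit_full.k - fit_nested.k
    p = float(stats.chi2.sf(stat, df)) if df > 0 else 1.0
    if stat == 0.0:
        p = 1.0
    return stat, df, p
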