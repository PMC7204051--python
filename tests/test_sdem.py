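"""Spatial Durbin error model: likelihood, estimation, impacts, selection."""

import numpy as np
import pandas as pd
import pytest

from lifespan.sdem import (
    ModelSpec,
    SpatialDurbinError,
    build_design,
    fit_sdem,
    impacts,
    log_jacobian,
    lr_test,
    profile_loglik,
    significance_stars,
)
from lifespan.synthetic import (
    LatticeConfig,
    TrueParameters,
    lattice_weights,
    simulate_covariates,
    simulate_sdem_outcome,
)
from lifespan.weights import AdjacencyList, row_standardize


def make_data(rows=10, cols=10, seed=1, p=2, truth=None):
    cfg = LatticeConfig(rows=rows, cols=cols, seed=seed, covariate_count=p)
    W = lattice_weights(cfg)
    X = simulate_covariates(cfg, W)
    truth = truth or TrueParameters(
        beta=(1.0, -0.5, 0.25, -0.2)[:p], theta=(0.3, 0.0, 0.1, -0.1)[:p]
    )
    y = simulate_sdem_outcome(X, W, truth, seed=seed + 1000)
    return y.to_numpy(), X, W, truth


class TestDesign:
    def test_column_counts_with_and_without_lag(self):
        y, X, W, _ = make_data(p=3)
        spec_l = ModelSpec("y", tuple(X.columns), include_lagged=True)
        spec_n = ModelSpec("y", tuple(X.columns), include_lagged=False)
        Z_l, labels_l, blocks_l = build_design(X, W, spec_l)
        Z_n, labels_n, _ = build_design(X, W, spec_n)
        assert Z_l.shape[1] == 1 + 2 * 3 and Z_n.shape[1] == 1 + 3
        assert labels_l[0] == "intercept" and np.all(Z_l[:, 0] == 1.0)
        assert blocks_l.count("direct") == 3 and blocks_l.count("lag") == 3
        assert labels_l[4:] == ["lag_x1", "lag_x2", "lag_x3"]

    def test_nonfinite_entry_named(self):
        y, X, W, _ = make_data()
        X = X.copy()
        X.iloc[3, 1] = np.nan
        with pytest.raises(ValueError, match="x2"):
            build_design(X, W, ModelSpec("y", tuple(X.columns)))

    def test_constant_covariate_makes_fit_rank_deficient(self):
        y, X, W, _ = make_data()
        X = X.copy()
        X["c"] = 1.0  # its lag equals it (and the intercept) on this island-free grid
        with pytest.raises(np.linalg.LinAlgError, match="rank"):
            fit_sdem(y, X, W)


class TestLogJacobian:
    def test_zero_lambda_gives_zero(self, grid5_weights):
        assert log_jacobian(0.0, grid5_weights.eigenvalues) == 0.0

    def test_two_tract_closed_form(self):
        assert log_jacobian(0.5, np.array([1.0, -1.0])) == pytest.approx(
            np.log(0.75), abs=1e-14
        )

    @pytest.mark.parametrize("lam", [-0.5, 0.0, 0.4, 0.9])
    @pytest.mark.parametrize("dims", [(3, 3), (5, 5), (10, 10)])
    def test_matches_dense_lu_determinant(self, lam, dims):
        W = lattice_weights(LatticeConfig(rows=dims[0], cols=dims[1], seed=0))
        direct = np.linalg.slogdet(np.eye(W.n) - lam * W.dense())[1]
        assert log_jacobian(lam, W.eigenvalues) == pytest.approx(direct, abs=1e-8)

    def test_inadmissible_lambda_raises(self, grid5_weights):
        with pytest.raises(ValueError):
            log_jacobian(1.5, grid5_weights.eigenvalues)


class TestProfileLikelihood:
    def test_at_zero_equals_ols_concentrated_loglik(self):
        import statsmodels.api as sm

        y, X, W, _ = make_data()
        Z, _, _ = build_design(X, W, ModelSpec("y", tuple(X.columns)))
        ours = profile_loglik(0.0, y, Z, W)
        assert ours == pytest.approx(sm.OLS(y, Z).fit().llf, abs=1e-8)

    def test_perfect_fit_guarded_with_infinity(self):
        y, X, W, _ = make_data()
        Z, _, _ = build_design(X, W, ModelSpec("y", tuple(X.columns)))
        y_exact = Z @ np.arange(1.0, Z.shape[1] + 1)
        assert profile_loglik(0.0, y_exact, Z, W) == np.inf

    def test_optimum_matches_fine_grid_search(self):
        y, X, W, _ = make_data(rows=5, cols=5, seed=9)
        Z, _, _ = build_design(X, W, ModelSpec("y", tuple(X.columns)))
        fit = fit_sdem(y, X, W)
        lo = 1.0 / W.eigenvalues.min() + 1e-6
        grid = np.arange(lo, 1.0 - 1e-6, 1e-4)
        lls = np.array([profile_loglik(l, y, Z, W) for l in grid])
        lam_grid = grid[np.argmax(lls)]
        # refine around the winner at 1e-6 steps
        fine = np.arange(lam_grid - 2e-4, lam_grid + 2e-4, 1e-6)
        fine = fine[(fine > lo) & (fine < 1 - 1e-6)]
        lam_fine = fine[np.argmax([profile_loglik(l, y, Z, W) for l in fine])]
        assert fit.lam == pytest.approx(lam_fine, abs=1e-4)

    def test_fitted_lambda_is_global_max_on_admissible_grid(self):
        y, X, W, _ = make_data(rows=6, cols=6, seed=3)
        Z, _, _ = build_design(X, W, ModelSpec("y", tuple(X.columns)))
        fit = fit_sdem(y, X, W)
        lo = 1.0 / W.eigenvalues.min() + 1e-6
        grid = np.linspace(lo, 1 - 1e-6, 200)
        ll_hat = profile_loglik(fit.lam, y, Z, W)
        assert all(ll_hat >= profile_loglik(l, y, Z, W) - 1e-9 for l in grid)


class TestFit:
    def test_ols_equivalence_at_fixed_lambda_zero(self):
        y, X, W, _ = make_data()
        spec = ModelSpec("y", tuple(X.columns), include_lagged=False)
        fit = fit_sdem(y, X, W, spec, fix_lambda=0.0)
        Z = np.column_stack([np.ones(len(y)), X.to_numpy()])
        beta_ols = np.linalg.solve(Z.T @ Z, Z.T @ y)
        assert np.allclose(fit.params["estimate"].to_numpy(), beta_ols, atol=1e-8)

    def test_sklearn_estimator_interface(self):
        from sklearn.base import clone

        y, X, W, _ = make_data()
        est = SpatialDurbinError(weights=W)
        est2 = clone(est)
        assert est2.get_params()["include_lagged"] is True
        est2.set_params(include_lagged=False).fit(X, y)
        assert est2.coef_.shape == (3,)
        pred = est2.predict(X)
        assert pred.shape == y.shape
        # trend prediction equals Z gamma_hat
        assert np.allclose(pred, est2.results_.fitted_trend)

    def test_aic_identity(self):
        y, X, W, _ = make_data()
        fit = fit_sdem(y, X, W)
        assert fit.aic == pytest.approx(2 * (fit.k + 2) - 2 * fit.loglik, abs=1e-10)

    def test_translation_equivariance(self):
        y, X, W, _ = make_data()
        f0 = fit_sdem(y, X, W)
        f1 = fit_sdem(y + 5.0, X, W)
        assert np.allclose(f1.fitted_trend, f0.fitted_trend + 5.0, atol=1e-7)
        assert np.allclose(
            f1.beta.to_numpy(), f0.beta.to_numpy(), atol=1e-8
        )
        assert np.allclose(f1.theta.to_numpy(), f0.theta.to_numpy(), atol=1e-8)
        assert f1.lam == pytest.approx(f0.lam, abs=1e-6)

    def test_covariate_scaling(self):
        y, X, W, _ = make_data()
        f0 = fit_sdem(y, X, W)
        X10 = X.copy()
        X10["x1"] = X10["x1"] * 10.0
        f1 = fit_sdem(y, X10, W)
        assert f1.beta["x1"] == pytest.approx(f0.beta["x1"] / 10.0, abs=1e-8)
        assert f1.params.loc["lag_x1", "estimate"] == pytest.approx(
            f0.params.loc["lag_x1", "estimate"] / 10.0, abs=1e-8
        )
        assert f1.loglik == pytest.approx(f0.loglik, abs=1e-6)

    def test_r_squared_is_squared_trend_correlation(self):
        y, X, W, _ = make_data()
        fit = fit_sdem(y, X, W)
        assert fit.r_squared == pytest.approx(
            np.corrcoef(y, fit.fitted_trend)[0, 1] ** 2, abs=1e-12
        )
        assert 0 <= fit.r_squared <= 1


class TestImpacts:
    def test_total_is_direct_plus_indirect_without_significance(self):
        y, X, W, _ = make_data()
        fit = fit_sdem(y, X, W)
        tab = impacts(fit).table
        assert np.allclose(
            tab["total"], tab["direct"] + tab["indirect"], atol=0
        )
        assert "total_p" not in tab.columns and "total_stars" not in tab.columns

    def test_reference_sum(self):
        # a direct effect of 0.13 and neighbor effect 0.06 total 0.19
        assert 0.13 + 0.06 == pytest.approx(0.19)

    def test_requires_lagged_block(self):
        y, X, W, _ = make_data()
        fit = fit_sdem(y, X, W, ModelSpec("y", tuple(X.columns), include_lagged=False))
        with pytest.raises(ValueError, match="lag"):
            impacts(fit)


class TestModelSelection:
    def test_identical_fits_give_zero_statistic_p_one(self):
        y, X, W, _ = make_data()
        fit = fit_sdem(y, X, W)
        # compare against itself through a nested copy with equal loglik
        nested = fit_sdem(y, X, W, ModelSpec("y", tuple(X.columns), include_lagged=False))
        stat, df, p = lr_test(fit, nested)
        assert df == 2 and stat >= 0.0 and 0 <= p <= 1

    def test_non_nested_specs_rejected(self):
        y, X, W, _ = make_data()
        f_ab = fit_sdem(y, X[["x1"]], W, ModelSpec("y", ("x1",)))
        f_b = fit_sdem(y, X[["x2"]], W, ModelSpec("y", ("x2",), include_lagged=False))
        with pytest.raises(ValueError, match="nested"):
            lr_test(f_ab, f_b)

    def test_stars_thresholds_inclusive(self):
        assert significance_stars(0.001) == "***"
        assert significance_stars(0.01) == "**"
        assert significance_stars(0.049) == "*"
        assert significance_stars(0.05) == "*"
        assert significance_stars(0.051) == ""


class TestAgainstIndependentGLSOracle:
    def test_coefficients_match_gls_at_fitted_lambda(self):
        """At the fitted lambda, coefficients must solve the GLS problem with
        covariance [(I-lam W)'(I-lam W)]^{-1}, computed independently."""
        y, X, W, _ = make_data(rows=7, cols=7, seed=5)
        fit = fit_sdem(y, X, W)
        A = np.eye(W.n) - fit.lam * W.dense()
        Z = np.column_stack(
            [np.ones(W.n), X.to_numpy(), W.dense() @ X.to_numpy()]
        )
        Sigma_inv = A.T @ A
        gls = np.linalg.solve(Z.T @ Sigma_inv @ Z, Z.T @ Sigma_inv @ y)
        assert np.allclose(fit.params["estimate"].to_numpy(), gls, atol=1e-8)
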