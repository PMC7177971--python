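"""Spatial Durbin maximum likelihood and impact estimation."""

import numpy as np
import pytest

from localuse import (
    DGPConfig,
    SDMFit,
    fit_sdm,
    gen_outcome,
    impacts_dense,
    impacts_mc,
    knn_weights,
    log_det,
)


def make_fit(rho, beta, theta, W, vcov_scale=0.0):
    """Hand-assembled SDMFit for impact computations."""
    beta = np.asarray(beta, dtype=float)
    theta = np.asarray(theta, dtype=float)
    d = len(beta) + len(theta) + 1
    return SDMFit(
        rho=rho,
        beta=beta,
        theta=theta,
        sigma2=1.0,
        vcov=vcov_scale * np.eye(d),
        loglik=0.0,
        residuals=np.zeros(W.n),
        iv_names=tuple(f"x{j}" for j in range(len(theta))),
        rho_interval=W.rho_interval(),
    )


class TestLogDet:
    def test_zero_at_rho_zero(self, medium_weights):
        assert log_det(0.0, medium_weights) == 0.0

    def test_matches_direct_determinant_3x3(self):
        coords = np.array([[0.0, 0], [1, 0], [3, 0]])
        W = knn_weights(coords, k=1)
        for rho in (-0.5, 0.3, 0.8):
            direct = np.linalg.slogdet(np.eye(3) - rho * W.matrix.toarray())[1]
            assert log_det(rho, W) == pytest.approx(direct, abs=1e-12)

    def test_matches_direct_determinant_asymmetric(self, medium_weights):
        Wd = medium_weights.matrix.toarray()
        for rho in (-0.4, 0.6, 0.9):
            direct = np.linalg.slogdet(np.eye(100) - rho * Wd)[1]
            assert log_det(rho, medium_weights) == pytest.approx(direct, abs=1e-8)

    def test_feasible_upper_bound_is_one(self, medium_weights):
        assert medium_weights.rho_interval()[1] == 1.0
        with pytest.raises(ValueError):
            log_det(1.5, medium_weights)


class TestFitSDM:
    def test_collapses_to_ols_without_spatial_process(self, medium_weights):
        # in the noiseless nonspatial limit rho is unidentified (exact
        # likelihood ridge: intercept and theta reparameterize rho), but
        # the slope coefficients and total impacts equal the OLS solution
        rng = np.random.default_rng(2)
        n = medium_weights.n
        X = rng.normal(size=(n, 2))
        y = 0.3 + X @ np.array([1.0, -0.5]) + rng.normal(0, 1e-7, n)
        fit = fit_sdm(y, X, medium_weights)
        Z = np.column_stack([np.ones(n), X, medium_weights.matrix @ X])
        ols, *_ = np.linalg.lstsq(Z, y, rcond=None)
        assert np.allclose(fit.beta[1:], ols[1:3], atol=1e-6)
        totals = (fit.beta[1:] + fit.theta) / (1 - fit.rho)
        assert np.allclose(totals, [1.0, -0.5], atol=1e-6)
        # with real residual noise, rho concentrates near 0
        y2 = 0.3 + X @ np.array([1.0, -0.5]) + rng.normal(0, 0.5, n)
        fit2 = fit_sdm(y2, X, medium_weights)
        assert abs(fit2.rho) < 0.3

    def test_loglik_at_optimum_beats_rho_zero(self, medium_weights, simple_dgp):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(medium_weights.n, 2))
        y = gen_outcome(X, medium_weights, simple_dgp, seed=4)
        fit = fit_sdm(y, X, medium_weights)
        # constrained rho=0 model is plain OLS on the Durbin design
        n = medium_weights.n
        Z = np.column_stack([np.ones(n), X, medium_weights.matrix @ X])
        coef, *_ = np.linalg.lstsq(Z, y, rcond=None)
        rss = float(np.sum((y - Z @ coef) ** 2))
        ll0 = -0.5 * n * (np.log(rss / n) + 1 + np.log(2 * np.pi))
        assert fit.loglik >= ll0 - 1e-8

    def test_matches_grid_search_oracle(self):
        """Concentrated optimizer agrees with a brute-force profile grid."""
        rng = np.random.default_rng(6)
        n = 60
        W = knn_weights(rng.uniform(0, 20, (n, 2)), k=3)
        dgp = DGPConfig(rho=0.5, beta=[1.0], theta=[0.5], sigma=0.3, moe_scale=[0.0])
        X = rng.normal(size=(n, 1))
        y = gen_outcome(X, W, dgp, seed=7)
        fit = fit_sdm(y, X, W)
        Z = np.column_stack([np.ones(n), X, W.matrix @ X])
        Wy = W.matrix @ y

        def profile(rho):
            coef, *_ = np.linalg.lstsq(Z, y - rho * Wy, rcond=None)
            rss = np.sum((y - rho * Wy - Z @ coef) ** 2)
            return log_det(rho, W) - 0.5 * n * np.log(rss / n)

        grid = np.linspace(-0.9, 0.99, 2000)
        rho_grid = grid[np.argmax([profile(r) for r in grid])]
        assert fit.rho == pytest.approx(rho_grid, abs=2e-3)

    def test_recovers_dgp_parameters(self, medium_weights):
        dgp = DGPConfig(
            rho=0.4, beta=[1.0, 0.5], theta=[0.5, -0.3], sigma=0.05, moe_scale=[0.0, 0.0]
        )
        rng = np.random.default_rng(8)
        X = rng.normal(size=(medium_weights.n, 2))
        y = gen_outcome(X, medium_weights, dgp, seed=9)
        fit = fit_sdm(y, X, medium_weights)
        assert fit.rho == pytest.approx(0.4, abs=0.1)
        assert np.allclose(fit.beta[1:], dgp.beta, atol=0.1)
        assert np.allclose(fit.theta, dgp.theta, atol=0.2)

    def test_permutation_invariance(self, medium_weights, simple_dgp):
        rng = np.random.default_rng(10)
        n = medium_weights.n
        X = rng.normal(size=(n, 2))
        y = gen_outcome(X, medium_weights, simple_dgp, seed=11)
        fit1 = fit_sdm(y, X, medium_weights)
        perm = rng.permutation(n)
        coords_orig = np.zeros((n, 2))  # rebuild W consistently from scratch
        Wp_neighbors = np.empty_like(medium_weights.neighbors)
        inv = np.empty(n, dtype=int)
        inv[perm] = np.arange(n)
        Wp_neighbors = inv[medium_weights.neighbors[perm]]
        from localuse import SpatialWeights

        Wp = SpatialWeights(neighbors=Wp_neighbors, k=3, ids=np.arange(n))
        fit2 = fit_sdm(y[perm], X[perm], Wp)
        assert fit2.rho == pytest.approx(fit1.rho, abs=1e-6)
        assert fit2.loglik == pytest.approx(fit1.loglik, abs=1e-6)
        assert np.allclose(fit2.beta, fit1.beta, atol=1e-6)

    def test_collinear_design_named(self, medium_weights):
        rng = np.random.default_rng(12)
        n = medium_weights.n
        x = rng.normal(size=n)
        X = np.column_stack([x, 2 * x])
        with pytest.raises(ValueError, match="collinear"):
            fit_sdm(rng.normal(size=n), X, medium_weights)

    def test_too_few_units_rejected(self):
        W = knn_weights(np.random.default_rng(0).uniform(0, 5, (6, 2)), k=3)
        with pytest.raises(ValueError, match="too small"):
            fit_sdm(np.zeros(6), np.zeros((6, 2)), W)


class TestImpacts:
    def test_no_spatial_process_gives_beta(self, medium_weights):
        fit = make_fit(0.0, [0.0, 1.2, -0.4], [0.0, 0.0], medium_weights)
        imp = impacts_dense(fit, medium_weights)
        assert imp["x0"]["direct"] == pytest.approx(1.2)
        assert imp["x0"]["indirect"] == pytest.approx(0.0, abs=1e-14)
        assert imp["x1"]["total"] == pytest.approx(-0.4)

    def test_total_closed_form_row_standardized(self, medium_weights):
        fit = make_fit(0.5, [0.0, 1.0], [0.5], medium_weights)
        imp = impacts_dense(fit, medium_weights)
        assert imp["x0"]["total"] == pytest.approx(3.0, abs=1e-10)

    def test_mc_with_zero_vcov_is_constant_and_matches_dense(self, medium_weights):
        rng = np.random.default_rng(13)
        fit = make_fit(0.6, [0.1, 0.8], [-0.3], medium_weights)
        draws = impacts_mc(fit, medium_weights, n_draws=25, rng=rng)
        assert draws.n_draws == 25
        assert np.ptp(draws.total) == 0.0 and np.ptp(draws.direct) == 0.0
        dense = impacts_dense(fit, medium_weights)["x0"]
        assert draws.direct[0, 0] == pytest.approx(dense["direct"], rel=1e-3)
        assert draws.total[0, 0] == pytest.approx(dense["total"], rel=1e-10)
        assert np.allclose(draws.total, draws.direct + draws.indirect)

    @pytest.mark.parametrize("rho", [-0.5, 0.0, 0.4, 0.8])
    def test_trace_series_matches_dense_oracle(self, medium_weights, rho):
        fit = make_fit(rho, [0.0, 1.0], [0.5], medium_weights)
        dense = impacts_dense(fit, medium_weights)["x0"]
        draws = impacts_mc(
            fit, medium_weights, n_draws=1, rng=np.random.default_rng(0), q=30
        )
        assert draws.direct[0, 0] == pytest.approx(dense["direct"], rel=1e-3)
        assert draws.indirect[0, 0] == pytest.approx(
            dense["indirect"], rel=1e-3, abs=1e-6
        )

    def test_mc_mean_near_dense_under_uncertainty(self, medium_weights):
        fit = make_fit(0.4, [0.0, 1.0], [0.5], medium_weights, vcov_scale=1e-4)
        draws = impacts_mc(
            fit, medium_weights, n_draws=400, rng=np.random.default_rng(14)
        )
        dense = impacts_dense(fit, medium_weights)["x0"]
        se = draws.total[:, 0].std() / np.sqrt(400)
        assert abs(draws.total[:, 0].mean() - dense["total"]) < 3 * se + 1e-3
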