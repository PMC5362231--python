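import itertools

import numpy as np
import pytest
from scipy.special import expit, logit

from occufit.model import (
    ModelSpec,
    UnfittableYearError,
    aic_compare,
    delta_method_se_psi,
    fit_model_c,
    negative_log_likelihood,
    predict_p,
    predict_psi,
    site_likelihood,
)

from conftest import make_dataset, simulate_simple


def enumeration_site_likelihood(y, psi, p):
    """Independent oracle: sum over the latent state z in {0, 1}."""
    y = np.asarray(y, dtype=float)
    p = np.broadcast_to(np.asarray(p, dtype=float), y.shape)
    mask = ~np.isnan(y)
    y, p = y[mask], p[mask]
    # z = 1 branch
    pr_occ = np.prod(np.where(y == 1, p, 1 - p))
    # z = 0 branch: impossible if any detection
    pr_unocc = 0.0 if np.any(y == 1) else 1.0
    return psi * pr_occ + (1 - psi) * pr_unocc


class TestSiteLikelihood:
    def test_detection_no_zero_inflation(self):
        assert site_likelihood([1, 0], 1.0, [0.5, 0.5]) == pytest.approx(0.25)

    def test_all_zero_enumeration_value(self):
        # 0.5 * 0.25 + 0.5 * 1 = 0.625
        assert site_likelihood([0, 0], 0.5, [0.5, 0.5]) == pytest.approx(0.625)

    def test_unoccupied_detection_impossible(self):
        assert site_likelihood([1, 0], 0.0, [0.5, 0.5]) == 0.0

    def test_missing_visits_skipped(self):
        assert site_likelihood([1, np.nan], 1.0, [0.5, 0.9]) == pytest.approx(0.5)

    @pytest.mark.parametrize("T", [1, 2, 3, 4])
    def test_exhaustive_enumeration_equivalence(self, T):
        rng = np.random.default_rng(T)
        for _ in range(100):
            psi = rng.uniform(0.01, 0.99)
            p = rng.uniform(0.01, 0.99, T)
            for bits in itertools.product([0, 1], repeat=T):
                y = np.array(bits, dtype=float)
                assert site_likelihood(y, psi, p) == pytest.approx(
                    enumeration_site_likelihood(y, psi, p), abs=1e-10
                )


class TestNegativeLogLikelihood:
    def test_duplicated_sites_double_nll(self):
        rng = np.random.default_rng(0)
        y, _ = simulate_simple(rng, 30, 4, 0.6, 0.3)
        ds = make_dataset(y)
        ds2 = make_dataset(np.vstack([y, y]))
        theta = np.array([0.3, -0.4])
        assert negative_log_likelihood(theta, ds2) == pytest.approx(
            2 * negative_log_likelihood(theta, ds), rel=1e-12
        )

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(1)
        y, _ = simulate_simple(rng, 20, 3, 0.5, 0.4)
        x = rng.standard_normal(20)
        ds = make_dataset(y, x=x)
        spec = ModelSpec(occupancy_terms=("x",))
        theta = np.array([0.2, 0.5, -0.3])
        psi = expit(theta[0] + theta[1] * x)
        p = expit(theta[2])
        oracle = -sum(
            np.log(enumeration_site_likelihood(y[i], psi[i], np.full(3, p)))
            for i in range(20)
        )
        assert negative_log_likelihood(theta, ds, spec) == pytest.approx(
            oracle, abs=1e-10
        )

    def test_boundary_all_detections(self):
        y = np.ones((10, 3))
        ds = make_dataset(y)
        assert negative_log_likelihood([20.0, 20.0], ds) == pytest.approx(0.0, abs=1e-6)

    def test_invariant_to_site_order(self):
        rng = np.random.default_rng(2)
        y, _ = simulate_simple(rng, 25, 4, 0.5, 0.3)
        perm = rng.permutation(25)
        theta = [0.1, 0.2]
        assert negative_log_likelihood(theta, make_dataset(y)) == pytest.approx(
            negative_log_likelihood(theta, make_dataset(y[perm])), rel=1e-12
        )

    def test_invariant_to_missing_padding(self):
        rng = np.random.default_rng(3)
        y, _ = simulate_simple(rng, 25, 4, 0.5, 0.3)
        padded = np.hstack([y, np.full((25, 2), np.nan)])
        theta = [0.1, 0.2]
        assert negative_log_likelihood(theta, make_dataset(y)) == pytest.approx(
            negative_log_likelihood(theta, make_dataset(padded)), rel=1e-12
        )

    def test_gradient_matches_finite_differences(self):
        from occufit.model import _nll_grad, _prepare_arrays

        rng = np.random.default_rng(4)
        y, _ = simulate_simple(rng, 30, 4, 0.6, 0.3)
        x = rng.standard_normal(30)
        ll = rng.uniform(0, 1.5, (30, 4))
        ds = make_dataset(y, x=x, visit_covariates={"ll": ll})
        spec = ModelSpec(occupancy_terms=("x",), detection_terms=("ll",))
        arrays = _prepare_arrays(ds, spec)
        theta = rng.normal(0, 0.5, 4)
        _, grad = _nll_grad(theta, *arrays)
        eps = 1e-6
        for j in range(4):
            step = np.zeros(4)
            step[j] = eps
            num = (
                _nll_grad(theta + step, *arrays)[0]
                - _nll_grad(theta - step, *arrays)[0]
            ) / (2 * eps)
            assert grad[j] == pytest.approx(num, rel=1e-5, abs=1e-7)


def grid_search_intercept_only(y, step=0.001):
    """Independent oracle: exhaustive 2-D grid over (psi, p) at the given step."""
    d = np.nansum(y, axis=1)
    T = (~np.isnan(y)).sum(axis=1)
    allzero = (d == 0).astype(float)
    grid = np.arange(step, 1.0, step)
    # history probability given occupancy, per (p, site); independent of psi
    A = np.exp(
        d[None, :] * np.log(grid)[:, None]
        + (T - d)[None, :] * np.log1p(-grid)[:, None]
    )
    best = (np.inf, None, None)
    for psi in grid:
        nll = -np.log(psi * A + (1.0 - psi) * allzero[None, :]).sum(axis=1)
        j = int(np.argmin(nll))
        if nll[j] < best[0]:
            best = (float(nll[j]), float(psi), float(grid[j]))
    return best


class TestFitModelC:
    def test_intercept_only_matches_grid_oracle(self):
        rng = np.random.default_rng(10)
        y, _ = simulate_simple(rng, 50, 4, 0.6, 0.4)
        fit = fit_model_c(make_dataset(y), n_starts=3, seed=0)
        _, psi_grid, p_grid = grid_search_intercept_only(y)
        assert expit(fit.beta[0]) == pytest.approx(psi_grid, abs=0.002)
        assert expit(fit.alpha[0]) == pytest.approx(p_grid, abs=0.002)

    def test_no_detections_raises(self):
        y = np.zeros((20, 4))
        with pytest.raises(UnfittableYearError):
            fit_model_c(make_dataset(y))

    def test_parameter_recovery_coverage(self):
        # estimates within 2 SEs of truth in >= 90% of seeded replicates
        hits = 0
        n_rep = 100
        truth = np.array([logit(0.6), logit(0.3)])
        for rep in range(n_rep):
            rng = np.random.default_rng(1000 + rep)
            y, _ = simulate_simple(rng, 1000, 10, 0.6, 0.3)
            fit = fit_model_c(make_dataset(y), n_starts=1, seed=rep)
            se = np.sqrt(np.diag(fit.vcov))
            if np.all(np.abs(fit.theta - truth) <= 2 * se):
                hits += 1
        assert hits / n_rep >= 0.90

    def test_aic_identity(self):
        rng = np.random.default_rng(11)
        y, _ = simulate_simple(rng, 50, 4, 0.6, 0.4)
        fit = fit_model_c(make_dataset(y), seed=1)
        assert fit.aic == pytest.approx(2 * fit.n_params - 2 * fit.loglik)

    def test_vcov_symmetric(self):
        rng = np.random.default_rng(12)
        y, _ = simulate_simple(rng, 80, 5, 0.5, 0.35)
        fit = fit_model_c(make_dataset(y), seed=1)
        assert np.allclose(fit.vcov, fit.vcov.T)

    def test_slope_bias_small_at_large_s(self):
        # on data simulated from the fitted class, slope bias shrinks with S
        errors = []
        for rep in range(12):
            rng = np.random.default_rng(300 + rep)
            x = rng.standard_normal(5000)
            y, _ = simulate_simple(rng, 5000, 5, 0.5, 0.3, x=x, beta1=0.5)
            fit = fit_model_c(
                make_dataset(y, x=x), ModelSpec(occupancy_terms=("x",)),
                n_starts=1, seed=rep,
            )
            errors.append(fit.beta[1] - 0.5)
        mc_se = np.std(errors, ddof=1) / np.sqrt(len(errors))
        assert abs(np.mean(errors)) <= 3 * mc_se + 0.01


@pytest.fixture(scope="module")
def fit():
    rng = np.random.default_rng(20)
    x = rng.standard_normal(400)
    y, _ = simulate_simple(rng, 400, 5, 0.5, 0.4, x=x, beta1=0.8)
    return fit_model_c(
        make_dataset(y, x=x), ModelSpec(occupancy_terms=("x",)), seed=0
    )


class TestPredict:

    def test_zero_covariates_give_intercept(self, fit):
        psi = predict_psi(fit, np.zeros((3, 1)))
        assert np.allclose(psi, expit(fit.beta[0]))

    def test_monotone_in_positive_coefficient(self, fit):
        assert fit.beta[1] > 0
        psi = predict_psi(fit, np.linspace(-2, 2, 9)[:, None])
        assert np.all(np.diff(psi) > 0)

    def test_missing_column_raises(self, fit):
        import pandas as pd

        with pytest.raises(ValueError, match="missing covariate"):
            predict_psi(fit, pd.DataFrame({"wrong": [0.0]}))

    def test_predict_p_intercept_only(self, fit):
        p = predict_p(fit, shape=(2, 3))
        assert np.allclose(p, expit(fit.alpha[0]))

    def test_predict_p_hand_computed(self):
        rng = np.random.default_rng(21)
        y, _ = simulate_simple(rng, 200, 2, 0.6, 0.5)
        ll = rng.uniform(0, 2, (200, 2))
        ds = make_dataset(y, visit_covariates={"ll": ll})
        fit = fit_model_c(ds, ModelSpec(detection_terms=("ll",)), seed=0)
        hand = expit(fit.alpha[0] + fit.alpha[1] * ll)
        assert np.allclose(predict_p(fit, {"ll": ll}), hand)

    def test_predict_p_monotone(self):
        rng = np.random.default_rng(22)
        # detection driven up by the covariate
        x = np.tile(np.arange(5.0), (300, 1))
        z = rng.random(300) < 0.7
        p_true = expit(-1.5 + 0.8 * x)
        y = ((rng.random((300, 5)) < p_true) & z[:, None]).astype(float)
        ds = make_dataset(y, visit_covariates={"g": x})
        fit = fit_model_c(ds, ModelSpec(detection_terms=("g",)), seed=0)
        assert fit.alpha[1] > 0
        grid = {"g": np.arange(5.0)[None, :]}
        assert np.all(np.diff(predict_p(fit, grid)) > 0)


class TestAicCompare:
    def test_identical_fit_delta_zero(self):
        rng = np.random.default_rng(30)
        y, _ = simulate_simple(rng, 60, 4, 0.5, 0.4)
        fit = fit_model_c(make_dataset(y), seed=0)
        table = aic_compare([fit, fit])
        assert np.allclose(table["delta_aic"], 0.0)

    def test_true_covariate_wins(self):
        rng = np.random.default_rng(31)
        x = rng.standard_normal(2000)
        y, _ = simulate_simple(rng, 2000, 6, 0.5, 0.4, x=x, beta1=1.0)
        ds = make_dataset(y, x=x)
        with_cov = fit_model_c(ds, ModelSpec(occupancy_terms=("x",)), seed=0)
        without = fit_model_c(ds, ModelSpec(), seed=0)
        table = aic_compare([without, with_cov])
        assert table.loc[0, "label"] == "x"
        assert table.loc[1, "delta_aic"] > 10

    def test_noise_covariate_costs_about_two(self):
        deltas = []
        for rep in range(10):
            rng = np.random.default_rng(600 + rep)
            noise = rng.standard_normal(400)
            y, _ = simulate_simple(rng, 400, 5, 0.5, 0.4)
            ds = make_dataset(y, x=noise)
            small = fit_model_c(ds, ModelSpec(), seed=0)
            big = fit_model_c(ds, ModelSpec(occupancy_terms=("x",)), seed=0)
            deltas.append(big.aic - small.aic)
        assert 0 < np.mean(deltas) < 3

    def test_mismatched_datasets_error(self):
        rng = np.random.default_rng(33)
        y1, _ = simulate_simple(rng, 40, 4, 0.5, 0.4)
        y2, _ = simulate_simple(rng, 40, 4, 0.5, 0.4)
        f1 = fit_model_c(make_dataset(y1), seed=0)
        f2 = fit_model_c(make_dataset(y2), seed=0)
        with pytest.raises(ValueError, match="different datasets"):
            aic_compare([f1, f2])


class TestDeltaMethod:
    def _fit(self):
        rng = np.random.default_rng(40)
        x = rng.standard_normal(500)
        y, _ = simulate_simple(rng, 500, 5, 0.5, 0.4, x=x, beta1=0.6)
        return fit_model_c(
            make_dataset(y, x=x), ModelSpec(occupancy_terms=("x",)), seed=0
        )

    def test_zero_vcov_gives_zero_se(self):
        fit = self._fit()
        fit.vcov = np.zeros_like(fit.vcov)
        se = delta_method_se_psi(fit, np.zeros((4, 1)))
        assert np.allclose(se, 0.0)

    def test_half_psi_unit_variance(self):
        fit = self._fit()
        fit.beta = np.array([0.0, 0.0])
        fit.vcov = np.eye(fit.vcov.shape[0])
        se = delta_method_se_psi(fit, np.zeros((1, 1)))
        assert se[0] == pytest.approx(0.25)

    def test_against_monte_carlo_oracle(self):
        fit = self._fit()
        W_new = np.array([[0.5], [-1.0], [0.0]])
        se = delta_method_se_psi(fit, W_new)
        rng = np.random.default_rng(99)
        ko = fit.beta.size
        draws = rng.multivariate_normal(fit.beta, fit.vcov[:ko, :ko], size=10**5)
        X = np.column_stack([np.ones(3), W_new])
        psi_draws = expit(draws @ X.T)
        mc_sd = psi_draws.std(axis=0, ddof=1)
        assert np.allclose(se, mc_sd, rtol=0.05)
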