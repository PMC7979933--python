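"""GWR estimator: kernels, adaptive bandwidth, local solves against an
independent oracle, AICc, bandwidth selection, and prediction."""

import numpy as np
import pytest
import statsmodels.api as sm

from socgwr import (
    GWRConfig,
    adaptive_bandwidth,
    boxcox_invert,
    BoxCoxTransform,
    compute_aicc,
    fit_gwr,
    fit_local,
    kernel_weight,
    predict_gwr,
    select_bandwidth,
)
from socgwr.errors import (
    InvalidArgumentError,
    OversmoothingError,
    SingularFitError,
)

from conftest import wls_oracle


def random_instance(seed, n=50, p=3):
    rng = np.random.default_rng(seed)
    coords = rng.uniform(0, 1000, (n, 2))
    X = np.column_stack([np.ones(n), rng.standard_normal((n, p - 1))])
    beta = rng.standard_normal(p)
    z = X @ beta + rng.normal(0, 0.3, n)
    return X, z, coords


class TestKernels:
    def test_zero_distance_gives_unit_weight(self):
        assert kernel_weight(0.0, 5.0, "bisquare") == 1.0
        assert kernel_weight(0.0, 5.0, "gaussian") == 1.0

    def test_bisquare_support_boundary(self):
        assert kernel_weight(5.0, 5.0, "bisquare") == 0.0
        assert kernel_weight(6.0, 5.0, "bisquare") == 0.0

    def test_gaussian_at_bandwidth(self):
        assert kernel_weight(5.0, 5.0, "gaussian") == pytest.approx(np.exp(-0.5))

    def test_invalid_bandwidth(self):
        with pytest.raises(InvalidArgumentError):
            kernel_weight(1.0, 0.0, "bisquare")


class TestAdaptiveBandwidth:
    def test_colinear_points_sorted_distance(self):
        coords = np.array([[0.0, 0], [1, 0], [2, 0], [3, 0]])
        assert adaptive_bandwidth([0.0, 0.0], coords, k=3) == pytest.approx(2.0)

    def test_k_equal_n_gives_max_distance(self):
        coords = np.array([[0.0, 0], [1, 0], [2, 0], [7, 0]])
        assert adaptive_bandwidth([0.0, 0.0], coords, k=4) == pytest.approx(7.0)

    def test_coincident_point_floor(self):
        coords = np.array([[0.0, 0], [100.0, 100.0]])
        b = adaptive_bandwidth([0.0, 0.0], coords, k=1)
        assert b > 0  # floored at 1e-9 of the domain diagonal

    def test_empty_calibration_set(self):
        with pytest.raises(InvalidArgumentError):
            adaptive_bandwidth([0.0, 0.0], np.empty((0, 2)), k=1)


class TestFitLocal:
    def test_uniform_weights_reduce_to_ols(self):
        X, z, _ = random_instance(0)
        beta, _ = fit_local(X, z, np.ones(len(z)))
        ols = sm.OLS(z, X).fit().params
        np.testing.assert_allclose(beta, ols, atol=1e-8)

    def test_weights_on_p_points_interpolate(self):
        X, z, _ = random_instance(1, n=20, p=3)
        w = np.zeros(20)
        w[[3, 8, 15]] = 1.0
        beta, _ = fit_local(X, z, w)
        exact = np.linalg.solve(X[[3, 8, 15]], z[[3, 8, 15]])
        np.testing.assert_allclose(beta, exact, atol=1e-8)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_independent_wls_route(self, seed):
        X, z, _ = random_instance(seed)
        rng = np.random.default_rng(100 + seed)
        w = rng.uniform(0.01, 1.0, len(z))
        beta, _ = fit_local(X, z, w)
        np.testing.assert_allclose(beta, wls_oracle(X, z, w), atol=1e-8)

    def test_too_few_positive_weights(self):
        X, z, _ = random_instance(2)
        w = np.zeros(len(z))
        w[0] = 1.0
        with pytest.raises(SingularFitError):
            fit_local(X, z, w)

    def test_singularity_without_jitter_raises(self):
        X = np.column_stack([np.ones(10), np.ones(10)])  # rank 1
        z = np.arange(10.0)
        with pytest.raises(SingularFitError):
            fit_local(X, z, np.ones(10), ridge_jitter=0.0)
        beta, _ = fit_local(X, z, np.ones(10), ridge_jitter=1e-8)
        assert np.all(np.isfinite(beta))


class TestAicc:
    def test_direct_evaluation(self):
        # 2n ln(sigma) vanishes at sigma = 1
        expect = 100 * np.log(2 * np.pi) + 100 * 110 / 88
        assert compute_aicc(100, 10.0, 1.0) == pytest.approx(expect)

    def test_doubling_sigma_adds_2n_ln2(self):
        a = compute_aicc(200, 12.0, 1.0)
        b = compute_aicc(200, 12.0, 2.0)
        assert b - a == pytest.approx(2 * 200 * np.log(2))

    def test_oversmoothing_guard(self):
        with pytest.raises(OversmoothingError):
            compute_aicc(10, 8.0, 1.0)


class TestSelectBandwidth:
    def test_degenerate_range_returns_that_k(self):
        X, z, coords = random_instance(3, n=40)
        cfg = GWRConfig(k_range=(25, 25))
        assert select_bandwidth(X, z, coords, cfg) == 25

    def test_constant_coefficients_prefer_global_bandwidth(self):
        # spatially constant truth: AICc should pick k near k_max
        rng = np.random.default_rng(4)
        n = 150
        coords = rng.uniform(0, 1000, (n, 2))
        X = np.column_stack([np.ones(n), rng.standard_normal((n, 2))])
        z = X @ np.array([2.0, 1.0, -1.0]) + rng.normal(0, 0.5, n)
        cfg = GWRConfig(k_range=(10, n))
        k = select_bandwidth(X, z, coords, cfg)
        assert k >= 0.9 * n

    def test_heterogeneous_coefficients_prefer_local_bandwidth(self, hetero_dataset):
        grid, stack, truth, obs, rec = hetero_dataset
        sub = obs.iloc[:400]
        X = np.column_stack(
            [np.ones(len(sub)), sub["temperature"], sub["precipitation"]]
        )
        z = rec.iloc[:400]["z"].to_numpy()
        cfg = GWRConfig(k_range=(10, len(sub)))
        k = select_bandwidth(X, z, sub[["x", "y"]].to_numpy(), cfg)
        assert k < len(sub) / 4


class TestFitPredict:
    def test_constant_truth_matches_ols_within_3_se(self):
        rng = np.random.default_rng(5)
        n = 200
        coords = rng.uniform(0, 1000, (n, 2))
        X = np.column_stack([np.ones(n), rng.standard_normal((n, 2))])
        z = X @ np.array([1.5, 0.8, -0.6]) + rng.normal(0, 0.4, n)
        fit = fit_gwr(X, z, coords, GWRConfig(k_range=(20, n)))
        res = sm.OLS(z, X).fit()
        for j in range(3):
            dev = np.abs(fit.local_coefficients[:, j] - res.params[j])
            assert (dev < 3 * res.bse[j] + 1e-12).all()

    def test_infinite_gaussian_bandwidth_equals_ols(self):
        X, z, coords = random_instance(6, n=80)
        diam = np.hypot(*(coords.max(0) - coords.min(0)))
        fit = fit_gwr(
            X, z, coords, GWRConfig(kernel="gaussian", fixed_bandwidth=1e6 * diam)
        )
        ols = sm.OLS(z, X).fit()
        np.testing.assert_allclose(
            fit.local_coefficients, np.tile(ols.params, (80, 1)), atol=1e-6
        )
        np.testing.assert_allclose(fit.fitted_z, ols.fittedvalues, atol=1e-6)

    def test_hat_trace_bounds_and_finite_aicc(self):
        X, z, coords = random_instance(7, n=60)
        fit = fit_gwr(X, z, coords, GWRConfig(k_range=(10, 60)))
        assert X.shape[1] <= fit.trace_S <= 60
        assert np.isfinite(fit.aicc)

    def test_prediction_at_calibration_point_is_fitted_value(self):
        X, z, coords = random_instance(8, n=60)
        fit = fit_gwr(X, z, coords, GWRConfig(k_range=(15, 60)))
        zp = predict_gwr(fit, coords[:5], X[:5])
        np.testing.assert_allclose(zp, fit.fitted_z[:5], atol=1e-10)

    def test_constant_response_predicts_back_transformed_constant(self):
        rng = np.random.default_rng(9)
        n = 40
        coords = rng.uniform(0, 100, (n, 2))
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        z = np.full(n, 3.0)
        fit = fit_gwr(X, z, coords, GWRConfig(k_range=(10, n)))
        bc = BoxCoxTransform(lambda_=0.5, loglik=0.0)
        pred = predict_gwr(fit, [[50.0, 50.0]], [[1.0, 0.3]], transform=bc)
        assert pred[0] == pytest.approx(boxcox_invert(3.0, 0.5))

    def test_hand_solved_toy_prediction(self):
        # 5-point toy with a fixed bandwidth: brute-force the weighted
        # normal equations by hand and compare
        coords = np.array([[0.0, 0], [1, 0], [0, 1], [1, 1], [2, 2]])
        X = np.column_stack([np.ones(5), np.array([0.0, 1, 2, 3, 4])])
        z = np.array([1.0, 2.0, 2.5, 4.0, 5.5])
        b = 3.0
        fit = fit_gwr(
            X, z, coords, GWRConfig(kernel="gaussian", fixed_bandwidth=b)
        )
        new = np.array([[0.5, 0.5]])
        d = np.hypot(*(coords - new[0]).T)
        w = np.exp(-0.5 * (d / b) ** 2)
        beta = wls_oracle(X, z, w)
        expect = beta @ np.array([1.0, 2.0])
        got = predict_gwr(fit, new, [[1.0, 2.0]])
        assert got[0] == pytest.approx(expect, abs=1e-8)

    def test_prediction_invariant_under_calibration_reordering(self):
        X, z, coords = random_instance(10, n=70)
        fit = fit_gwr(X, z, coords, GWRConfig(k_range=(15, 70)))
        perm = np.random.default_rng(0).permutation(70)
        fit2 = fit_gwr(X[perm], z[perm], coords[perm], GWRConfig(k_range=(15, 70)))
        new = np.array([[500.0, 500.0], [100.0, 900.0]])
        newX = np.array([[1.0, 0.5, -0.5], [1.0, -1.0, 0.2]])
        np.testing.assert_allclose(
            predict_gwr(fit, new, newX), predict_gwr(fit2, new, newX), atol=1e-8
        )

    def test_nan_predictors_propagate_to_missing(self):
        X, z, coords = random_instance(11, n=40)
        fit = fit_gwr(X, z, coords, GWRConfig(k_range=(10, 40)))
        newX = np.array([[1.0, np.nan, 0.0], [1.0, 0.1, 0.2]])
        out = predict_gwr(fit, [[10.0, 10.0], [20.0, 20.0]], newX)
        assert np.isnan(out[0]) and np.isfinite(out[1])


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(4))
    def test_local_coefficients_match_dense_wls(self, seed):
        X, z, coords = random_instance(seed, n=50)
        fit = fit_gwr(X, z, coords, GWRConfig(k_range=(12, 50)))
        D = np.hypot(
            *(coords[:, None, :] - coords[None, :, :]).transpose(2, 0, 1)
        )
        for i in range(50):
            b = np.sort(D[i])[fit.k_selected - 1]
            w = np.where(D[i] < b, (1 - (D[i] / b) ** 2) ** 2, 0.0)
            np.testing.assert_allclose(
                fit.local_coefficients[i], wls_oracle(X, z, w), atol=1e-8
            )
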