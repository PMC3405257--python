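"""RBF network: design matrix, OLS center selection, output layer, fitting."""

import numpy as np
import numpy.linalg as la
import pytest

from gsmodels import RBFNetwork, RBFNNConfig, rbf_design
from gsmodels.rbfnn import _ols_path, fit_output_layer, rbf_bandwidth_scale


class TestDesignMatrix:
    def test_zero_distance_gives_one(self, rng):
        X = rng.normal(0, 1, (5, 3))
        Z = rbf_design(X, X, h=0.7)
        np.testing.assert_allclose(np.diag(Z), 1.0)

    def test_closed_form_value(self):
        # h * ||x - c||^2 = 1  ->  z = e^-1
        Z = rbf_design(np.array([[1.0, 0.0]]), np.array([[0.0, 0.0]]), h=1.0)
        assert Z[0, 0] == pytest.approx(np.exp(-1.0))

    def test_doubling_h_squares_entries(self, rng):
        X = rng.normal(0, 1, (6, 4))
        C = rng.normal(0, 1, (3, 4))
        np.testing.assert_allclose(
            rbf_design(X, C, 2.0), rbf_design(X, C, 1.0) ** 2, atol=1e-12
        )

    def test_invalid_inputs(self, rng):
        X = rng.normal(0, 1, (4, 3))
        with pytest.raises(ValueError, match="positive"):
            rbf_design(X, X, h=0.0)
        with pytest.raises(ValueError, match="mismatch"):
            rbf_design(X, rng.normal(0, 1, (2, 5)), h=1.0)


class TestCenterSelection:
    def test_greedy_matches_brute_force_search(self, rng):
        """At every step the selected center attains the best error-reduction
        among all remaining candidates (exhaustive check, n = 12)."""
        n = 12
        X = rng.normal(0, 1, (n, 3))
        y = rng.normal(0, 1, n)
        yc = y - y.mean()
        Z = rbf_design(X, X, 0.7)
        sel, err, _, _ = _ols_path(Z, yc, 0.0, 5)

        chosen = []
        for step in range(5):
            best, best_gain = None, -np.inf
            for j in range(n):
                if j in chosen:
                    continue
                cols = Z[:, chosen + [j]]
                resid = yc - cols @ la.lstsq(cols, yc, rcond=None)[0]
                gain = 1 - resid @ resid / (yc @ yc)
                if gain > best_gain + 1e-12:
                    best, best_gain = j, gain
            chosen.append(best)
            assert abs(sum(err[: step + 1]) - best_gain) < 1e-8
        assert sel == chosen

    def test_full_selection_interpolates_distinct_points(self, rng):
        n = 25
        X = rng.normal(0, 1, (n, 4))
        y = rng.normal(0, 1, n)
        Z = rbf_design(X, X, 1.0)
        sel, err, _, _ = _ols_path(Z, y - y.mean(), 0.0, n)
        w0, w = fit_output_layer(y, X, np.array(sel), 1.0)
        sse = np.sum((y - (w0 + Z[:, sel] @ w)) ** 2)
        assert len(sel) == n
        assert sse < 1e-6

    def test_err_ratios_sum_below_one_and_sse_nonincreasing(self, rng):
        n = 40
        X = rng.normal(0, 1, (n, 5))
        y = X[:, 0] * X[:, 1] + rng.normal(0, 0.5, n)
        yc = y - y.mean()
        Z = rbf_design(X, X, 0.5)
        sel, err, _, _ = _ols_path(Z, yc, 0.0, n)
        assert all(e >= 0 for e in err)
        assert sum(err) <= 1 + 1e-9
        sse_path = (yc @ yc) * (1 - np.cumsum(err))
        assert np.all(np.diff(sse_path) <= 1e-9)

    def test_err_path_equals_nested_regression_r2(self, rng):
        """Cumulative error-reduction equals the R^2 of regressing centered y
        on the selected (non-orthogonalized) basis columns."""
        n = 15
        X = rng.normal(0, 1, (n, 3))
        y = rng.normal(0, 1, n)
        yc = y - y.mean()
        Z = rbf_design(X, X, 0.9)
        sel, err, _, _ = _ols_path(Z, yc, 0.0, 8)
        for m in range(1, len(sel) + 1):
            resid = yc - Z[:, sel[:m]] @ la.lstsq(Z[:, sel[:m]], yc, rcond=None)[0]
            r2 = 1 - resid @ resid / (yc @ yc)
            assert abs(sum(err[:m]) - r2) < 1e-8

    def test_duplicate_of_unselected_candidate_is_inert(self, rng):
        n = 14
        X = rng.normal(0, 1, (n, 3))
        y = rng.normal(0, 1, n)
        yc = y - y.mean()
        Z = rbf_design(X, X, 0.8)
        sel, err, _, _ = _ols_path(Z, yc, 0.0, 4)
        dup = [j for j in range(n) if j not in sel][0]
        Z_dup = np.column_stack([Z, Z[:, dup]])
        sel2, err2, _, _ = _ols_path(Z_dup, yc, 0.0, 4)
        assert sel2 == sel
        np.testing.assert_allclose(err2, err)


class TestOutputLayer:
    def test_constant_response(self, rng):
        X = rng.normal(0, 1, (10, 2))
        y = np.full(10, 3.3)
        w0, w = fit_output_layer(y, X, np.array([0, 4]), 1.0)
        assert w0 == pytest.approx(3.3)
        np.testing.assert_allclose(w, 0.0, atol=1e-10)

    def test_single_center_matches_simple_regression(self, rng):
        X = rng.normal(0, 1, (20, 3))
        y = rng.normal(0, 1, 20)
        w0, w = fit_output_layer(y, X, np.array([5]), 0.6)
        z = rbf_design(X, X[[5]], 0.6)[:, 0]
        slope = np.cov(z, y, ddof=1)[0, 1] / np.var(z, ddof=1)
        assert w[0] == pytest.approx(slope)
        assert w0 == pytest.approx(y.mean() - slope * z.mean())

    def test_residuals_orthogonal_to_basis(self, rng):
        X = rng.normal(0, 1, (25, 3))
        y = rng.normal(0, 1, 25)
        idx = np.array([1, 7, 12])
        w0, w = fit_output_layer(y, X, idx, 0.5)
        Z = rbf_design(X, X[idx], 0.5)
        r = y - w0 - Z @ w
        assert np.max(np.abs(Z.T @ r)) < 1e-8


class TestFullFit:
    def test_pure_noise_selects_few_neurons(self):
        """Null signal: few neurons and inner PMSE near var(y), over seeds."""
        counts, ratios = [], []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            X = rng.integers(0, 3, (100, 10)).astype(float)
            y = rng.normal(0, 1, 100)
            res = RBFNetwork(y, X, RBFNNConfig(seed=seed)).fit()
            counts.append(res.n_neurons)
            ratios.append(res.inner_pmse / y.var())
        assert np.mean(counts) <= 10  # <= 0.1 n on average
        assert abs(np.mean(ratios) - 1.0) < 0.2

    def test_recovers_smooth_function_in_1d(self):
        rng = np.random.default_rng(7)
        x = rng.uniform(-3, 3, (200, 1))

        def f(t):
            return (
                2 * np.exp(-2 * (t + 2) ** 2)
                - 1.5 * np.exp(-3 * t**2)
                + np.exp(-2 * (t - 2) ** 2)
            )

        y = f(x[:, 0]) + rng.normal(0, 0.05, 200)
        res = RBFNetwork(y, x, RBFNNConfig(seed=1)).fit()
        xt = rng.uniform(-3, 3, (300, 1))
        yt = f(xt[:, 0])
        pred = res.predict(xt)
        r2 = 1 - np.sum((yt - pred) ** 2) / np.sum((yt - yt.mean()) ** 2)
        assert r2 > 0.9

    def test_identical_seeds_identical_model(self, rng):
        X = rng.integers(0, 3, (60, 8)).astype(float)
        y = X[:, 0] - X[:, 3] + rng.normal(0, 0.5, 60)
        a = RBFNetwork(y, X, RBFNNConfig(seed=4)).fit()
        b = RBFNetwork(y, X, RBFNNConfig(seed=4)).fit()
        np.testing.assert_array_equal(a.center_indices, b.center_indices)
        np.testing.assert_array_equal(a.w, b.w)
        assert a.h == b.h

    def test_prediction_composes_design_and_weights(self, rng):
        X = rng.integers(0, 3, (50, 6)).astype(float)
        y = rng.normal(0, 1, 50)
        res = RBFNetwork(y, X, RBFNNConfig(seed=2)).fit()
        X_new = rng.integers(0, 3, (7, 6)).astype(float)
        manual = res.w0 + rbf_design(X_new, res.centers, res.h) @ res.w
        np.testing.assert_allclose(res.predict(X_new), manual, atol=1e-12)

    def test_far_inputs_predict_intercept(self, rng):
        X = rng.integers(0, 3, (40, 5)).astype(float)
        y = rng.normal(0, 1, 40)
        res = RBFNetwork(y, X, RBFNNConfig(seed=3)).fit()
        far = np.full((2, 5), 1e6)
        np.testing.assert_allclose(res.predict(far), res.w0, atol=1e-8)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            RBFNNConfig(rho=0.0)
        with pytest.raises(ValueError):
            RBFNNConfig(gamma_grid=())
        with pytest.raises(ValueError):
            RBFNNConfig(val_fraction=1.0)


class TestRKHSEquivalence:
    def test_design_matrix_matches_kernel_for_matched_bandwidth(self, rng):
        """With M = n neurons, centers = all training rows and identity output
        activation, the RBF design equals the RKHS kernel matrix built from
        the same (unstandardized) distances and matched bandwidth."""
        X = rng.integers(0, 3, (20, 6)).astype(float)
        h = 0.8 / rbf_bandwidth_scale(X)
        Z = rbf_design(X, X, h)
        d2 = (
            (X**2).sum(1)[:, None] + (X**2).sum(1)[None, :] - 2 * X @ X.T
        )
        K = np.exp(-h * np.maximum(d2, 0))
        np.testing.assert_allclose(Z, K, atol=1e-10)
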