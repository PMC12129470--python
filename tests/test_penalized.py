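import numpy as np
import pytest

from varsel.penalized import (
    PenaltySpec,
    alasso_weights,
    cd_fit,
    cross_validate,
    fit_path,
    kkt_residual,
    lambda_max,
    _ridge_path_fit,
    _standardize_train,
)

from conftest import orthogonal_design


def soft(z, t):
    return np.sign(z) * np.maximum(np.abs(z) - t, 0.0)


class TestPenaltySpec:
    def test_family_constraints(self):
        with pytest.raises(ValueError):
            PenaltySpec("scad", 0.1, gamma=2.0)
        with pytest.raises(ValueError):
            PenaltySpec("mcp", 0.1, gamma=1.0)
        with pytest.raises(ValueError):
            PenaltySpec("alasso", 0.1)   # weights required
        with pytest.raises(ValueError):
            PenaltySpec("lasso", -1.0)
        assert PenaltySpec("scad", 0.1).gamma == 3.7
        assert PenaltySpec("mcp", 0.1).gamma == 3.0


class TestCoordinateDescent:
    def test_lambda_zero_equals_ols(self, strong_signal):
        X, Y, _ = strong_signal
        icpt, coef = cd_fit(X, Y, PenaltySpec("lasso", 0.0))
        ols, *_ = np.linalg.lstsq(np.column_stack([np.ones(len(Y)), X]), Y, rcond=None)
        np.testing.assert_allclose(coef, ols[1:], atol=1e-6)
        assert icpt == pytest.approx(ols[0], abs=1e-6)

    def test_lambda_max_gives_null_solution(self, strong_signal):
        X, Y, _ = strong_signal
        lm = lambda_max(X, Y)
        for lam in (lm, 1.5 * lm):
            _, coef = cd_fit(X, Y, PenaltySpec("lasso", lam))
            assert np.all(coef == 0.0)
        # just below lambda_max at least one coefficient is active
        _, coef = cd_fit(X, Y, PenaltySpec("lasso", 0.95 * lm))
        assert np.any(coef != 0.0)

    @pytest.mark.parametrize("family", ["lasso", "scad", "mcp"])
    def test_orthogonal_design_closed_forms(self, family, rng):
        n, m = 64, 5
        X = orthogonal_design(n, m)
        beta = np.array([3.0, -1.2, 0.6, 0.15, 0.0])
        Y = X @ beta + 0.3 * rng.standard_normal(n)
        lam = 0.4
        spec = PenaltySpec(family, lam)
        _, coef = cd_fit(X, Y, spec)
        # independent univariate solution: v = x'x/n, z = x'y_c/n
        yc = Y - Y.mean()
        v = (n - 1) / n
        expected = np.empty(m)
        for j in range(m):
            z = X[:, j] @ yc / n
            if family == "lasso":
                expected[j] = soft(z, lam) / v
            elif family == "mcp":
                g = 3.0
                b = soft(z, lam) / (v - 1 / g)
                expected[j] = b if abs(b) <= g * lam else z / v
            else:
                g = 3.7
                b1 = soft(z, lam) / v
                if abs(b1) <= lam:
                    expected[j] = b1
                else:
                    b2 = soft(z, g * lam / (g - 1)) / (v - 1 / (g - 1))
                    expected[j] = b2 if abs(b2) <= g * lam else z / v
        np.testing.assert_allclose(coef, expected, atol=1e-6)

    @pytest.mark.parametrize("family,kw", [
        ("lasso", {}),
        ("enet", {"alpha_mix": 0.4}),
        ("scad", {}),
        ("mcp", {}),
    ])
    def test_kkt_residual_small(self, family, kw, small_dataset):
        lam = 0.3 * lambda_max(small_dataset.X, small_dataset.Y)
        spec = PenaltySpec(family, lam, **kw)
        _, coef = cd_fit(small_dataset.X, small_dataset.Y, spec)
        assert kkt_residual(small_dataset.X, small_dataset.Y, coef, spec) <= 1e-5

    def test_enet_alpha_one_equals_lasso(self, small_dataset):
        lambdas = np.geomspace(1.0, 0.01, 20) * lambda_max(small_dataset.X, small_dataset.Y)
        _, c_lasso = fit_path(small_dataset.X, small_dataset.Y, lambdas, PenaltySpec("lasso", 0.0))
        _, c_enet = fit_path(
            small_dataset.X, small_dataset.Y, lambdas, PenaltySpec("enet", 0.0, alpha_mix=1.0)
        )
        np.testing.assert_allclose(c_enet, c_lasso, atol=1e-8)

    def test_agrees_with_sklearn_lasso(self, strong_signal):
        from sklearn.linear_model import Lasso

        X, Y, _ = strong_signal
        # sklearn solves the same (1/2N) objective but without internal
        # standardization; feed it pre-standardized data to compare
        Xs, yc, mu, sd, ybar = _standardize_train(X, Y)
        lam = 0.1
        sk = Lasso(alpha=lam, fit_intercept=False, tol=1e-10).fit(Xs, yc)
        _, coef = cd_fit(Xs, yc, PenaltySpec("lasso", lam))
        # cd_fit re-standardizes, sd of standardized cols is 1, so comparable
        np.testing.assert_allclose(coef, sk.coef_, atol=1e-5)


class TestCrossValidation:
    def test_one_se_rule_and_determinism(self, small_dataset):
        cv1 = cross_validate(small_dataset.X, small_dataset.Y, "lasso", seed=5)
        cv2 = cross_validate(small_dataset.X, small_dataset.Y, "lasso", seed=5)
        assert cv1.lambda_1se >= cv1.lambda_min
        assert cv1.lambda_min == cv2.lambda_min
        assert np.array_equal(cv1.fold_assignment, cv2.fold_assignment)
        cv3 = cross_validate(small_dataset.X, small_dataset.Y, "lasso", seed=6)
        assert not np.array_equal(cv1.fold_assignment, cv3.fold_assignment)

    def test_signal_beats_null_model(self, strong_signal):
        X, Y, _ = strong_signal
        cv = cross_validate(X, Y, "lasso", seed=0)
        imin = int(np.argmin(cv.cv_error))
        assert cv.cv_error[imin] < cv.cv_error[0]   # grid starts at lambda_max

    def test_enet_searches_alpha(self, small_dataset):
        cv = cross_validate(small_dataset.X, small_dataset.Y, "enet", seed=1)
        assert 0.1 <= cv.alpha_mix <= 0.9

    def test_too_few_rows_rejected(self, rng):
        X = rng.standard_normal((5, 3))
        with pytest.raises(ValueError):
            cross_validate(X, rng.standard_normal(5), "lasso")


class TestAdaptiveWeights:
    def test_ridge_closed_form_helper(self, rng):
        X = rng.standard_normal((50, 4))
        Xs, yc, *_ = _standardize_train(X, rng.standard_normal(50))
        lam = 0.7
        beta = _ridge_path_fit(Xs, yc, [lam])[0]
        n = len(yc)
        direct = np.linalg.solve(Xs.T @ Xs / n + lam * np.eye(4), Xs.T @ yc / n)
        np.testing.assert_allclose(beta, direct, atol=1e-10)

    def test_equal_magnitudes_give_equal_weights(self):
        X = orthogonal_design(64, 4, seed=9)
        Y = X @ np.array([2.0, -2.0, 2.0, -2.0])
        w = alasso_weights(X, Y, seed=0)
        np.testing.assert_allclose(w, w[0], rtol=1e-8)

    def test_weights_inversely_proportional_to_coefficients(self):
        # orthogonal noiseless design: ridge shrinks every coefficient by
        # the same factor, so the weight ratio equals the inverse
        # coefficient ratio regardless of the CV-chosen penalty
        X = orthogonal_design(64, 4, seed=2)
        Y = X @ np.array([1.0, 2.0, 4.0, -1.0])
        w = alasso_weights(X, Y, seed=0)
        assert w[0] / w[1] == pytest.approx(2.0, rel=1e-8)
        assert w[1] / w[2] == pytest.approx(2.0, rel=1e-8)
        assert w[0] / w[3] == pytest.approx(1.0, rel=1e-8)

    def test_null_coefficient_maps_to_large_finite_weight(self, rng):
        X = rng.standard_normal((60, 3))
        X[:, 2] = X[:, 0]            # duplicated: ridge splits, stays finite
        Y = np.zeros(60)             # all-zero outcome: all ridge coefs zero
        Y[0] = 1e-300
        w = alasso_weights(X, rng.standard_normal(60) * 0 + 1e-12 * rng.standard_normal(60), seed=0)
        assert np.all(np.isfinite(w)) and np.all(w <= 1e12)
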