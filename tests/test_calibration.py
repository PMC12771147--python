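"""Linear and PLS1 calibration: oracles, invariants and figures of merit."""

import numpy as np
import pytest

from diaquant.calibration import (
    CalibrationMetrics,
    DegenerateFitError,
    LinearCalibration,
    PLSCalibration,
    SingularDesignError,
    calibration_metrics,
    loo_rmsecv,
    select_n_components,
)
from diaquant.synthgen import CALIBRATION_LEVELS


def _ols_coefficients(X, y):
    """Independent oracle: multiple OLS via the normal equations."""
    Xd = np.column_stack([np.ones(len(y)), X])
    return np.linalg.solve(Xd.T @ Xd, Xd.T @ y)


class TestLinearCalibration:
    def test_exact_line_recovered(self):
        conc = np.array([1.0, 2.0, 3.0, 4.0])
        fit = LinearCalibration(conc, 2 * conc + 1).fit()
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_constant_responses_degenerate(self):
        with pytest.raises(DegenerateFitError):
            LinearCalibration([1.0, 2.0, 3.0], [5.0, 5.0, 5.0]).fit()

    def test_identical_concentrations_singular(self):
        with pytest.raises(SingularDesignError):
            LinearCalibration([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])

    def test_noisy_curve_matches_normal_equations(self, rng):
        conc = np.repeat(CALIBRATION_LEVELS, 3)
        resp = 40.0 * conc + 0.01 + rng.normal(0, 0.005, conc.size)
        fit = LinearCalibration(conc, resp).fit()
        # closed-form sum-formula oracle
        n = conc.size
        sxy = np.sum(conc * resp) - np.sum(conc) * np.sum(resp) / n
        sxx = np.sum(conc**2) - np.sum(conc) ** 2 / n
        slope = sxy / sxx
        intercept = resp.mean() - slope * conc.mean()
        assert fit.slope == pytest.approx(slope, rel=1e-12)
        assert fit.intercept == pytest.approx(intercept, rel=1e-12)

    def test_inverse_prediction_recovers_standards(self):
        conc = np.array(CALIBRATION_LEVELS)
        fit = LinearCalibration(conc, 37.5 * conc + 0.002).fit()
        assert np.allclose(fit.predict(37.5 * conc + 0.002), conc)

    def test_negative_prediction_returned_unclipped(self):
        conc = np.array([1.0, 2.0, 3.0])
        fit = LinearCalibration(conc, conc).fit()
        assert fit.predict(-0.5)[0] == pytest.approx(-0.5)

    def test_summary_mentions_slope_and_r_squared(self):
        conc = np.array([1.0, 2.0, 3.0, 4.0])
        text = LinearCalibration(conc, 2 * conc + 1).fit().summary()
        assert "slope" in text and "R-squared" in text


class TestPLSCalibration:
    def test_single_feature_collapses_to_ols(self):
        conc = np.repeat(CALIBRATION_LEVELS, 2)
        x = 30.0 * conc + 0.01  # exact line: direct and inverse fits coincide
        pls = PLSCalibration(x[:, None], conc, n_components=1).fit()
        lin = LinearCalibration(conc, x).fit()
        assert np.allclose(pls.predict(x[:, None]), lin.predict(x), atol=1e-12)

    def test_full_rank_equals_multiple_ols(self, rng):
        X = rng.normal(size=(7, 3))
        y = X @ np.array([0.5, -1.2, 2.0]) + 0.3 + rng.normal(0, 0.1, 7)
        pls = PLSCalibration(X, y, n_components=3).fit()
        beta = _ols_coefficients(X, y)
        yhat_ols = beta[0] + X @ beta[1:]
        assert np.allclose(pls.predict(X), yhat_ols, atol=1e-8)

    def test_first_weight_proportional_to_xty(self, rng):
        X = rng.normal(size=(10, 4))
        y = rng.normal(size=10)
        pls = PLSCalibration(X, y, n_components=2).fit()
        xty = (X - X.mean(0)).T @ (y - y.mean())
        cos = xty @ pls.weights[:, 0] / np.linalg.norm(xty)
        assert cos == pytest.approx(1.0, abs=1e-12)

    def test_regression_vector_equals_deflation_route(self, rng):
        X = rng.normal(size=(9, 5))
        y = rng.normal(size=9)
        pls = PLSCalibration(X, y, n_components=3).fit()
        Xnew = rng.normal(size=(6, 5))
        assert np.allclose(pls.predict(Xnew), pls.predict_via_deflation(Xnew), atol=1e-9)

    def test_matches_sklearn_nipals(self, rng):
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        X = rng.normal(size=(12, 4))
        y = X @ np.array([1.0, 0.5, -0.3, 0.2]) + rng.normal(0, 0.2, 12)
        ours = PLSCalibration(X, y, n_components=2).fit()
        ref = sklearn.PLSRegression(n_components=2, scale=False).fit(X, y)
        assert np.allclose(ours.predict(X), ref.predict(X).ravel(), atol=1e-8)

    def test_feature_reordering_leaves_predictions_unchanged(self, rng):
        X = rng.normal(size=(8, 3))
        y = rng.normal(size=8)
        perm = [2, 0, 1]
        a = PLSCalibration(X, y, n_components=2).fit()
        b = PLSCalibration(X[:, perm], y, n_components=2).fit()
        Xnew = rng.normal(size=(4, 3))
        assert np.allclose(a.predict(Xnew), b.predict(Xnew[:, perm]), atol=1e-10)

    def test_dimension_errors(self, rng):
        X = rng.normal(size=(5, 3))
        y = rng.normal(size=5)
        with pytest.raises(ValueError):
            PLSCalibration(X, y, n_components=4)
        pls = PLSCalibration(X, y, n_components=2).fit()
        with pytest.raises(ValueError):
            pls.predict(rng.normal(size=(2, 4)))

    def test_zero_variance_features_rejected(self):
        X = np.ones((5, 3))
        with pytest.raises(DegenerateFitError):
            PLSCalibration(X, np.arange(5.0), n_components=1)


class TestComponentSelection:
    def test_single_latent_factor_selects_one(self, rng):
        t = rng.normal(size=20)
        X = np.outer(t, [1.0, 2.0, -1.0]) + rng.normal(0, 1e-6, (20, 3))
        y = 3.0 * t
        assert select_n_components(X, y) == 1

    def test_three_factor_mixture_selects_three(self, rng):
        n = 24
        C = rng.uniform(0.1, 1.0, size=(n, 3))  # three concentration-linked factors
        S = np.array(
            [[1.0, 0.8, 0.1, 0.0, 0.3],
             [0.2, 1.0, 0.9, 0.2, 0.0],
             [0.0, 0.1, 0.7, 1.0, 0.6]]
        )
        X = C @ S + rng.normal(0, 1e-4, (n, 5))
        y = C @ np.array([1.0, -0.5, 0.8])
        assert select_n_components(X, y) == 3

    def test_pure_noise_selects_one(self, rng):
        X = rng.normal(size=(15, 4))
        y = rng.normal(size=15)
        assert select_n_components(X, y) == 1

    def test_rmsecv_deterministic(self, rng):
        X = rng.normal(size=(10, 3))
        y = rng.normal(size=10)
        assert np.array_equal(loo_rmsecv(X, y), loo_rmsecv(X, y))


class TestCalibrationMetrics:
    def test_perfect_model_zeroes(self):
        conc = np.array(CALIBRATION_LEVELS)
        fit = LinearCalibration(conc, 10 * conc).fit()
        m = calibration_metrics(fit, 10 * conc, conc, 10 * conc, conc)
        assert m.rmsec == pytest.approx(0.0, abs=1e-15)
        assert m.bias == pytest.approx(0.0, abs=1e-15)
        assert m.relative_error_pct == pytest.approx(0.0, abs=1e-9)
        assert m.r_squared == pytest.approx(1.0)

    def test_constant_offset_gives_bias_and_rmsep(self):
        class Shifted:
            def predict(self, X):
                return np.asarray(X, dtype=float).ravel() + 0.25

        y = np.array([1.0, 2.0, 3.0])
        m = calibration_metrics(Shifted(), y, y, y, y)
        assert m.bias == pytest.approx(0.25)
        assert m.rmsep == pytest.approx(0.25)

    def test_metrics_match_loop_oracle(self, rng):
        class Identity:
            def predict(self, X):
                return np.asarray(X, dtype=float).ravel()

        y = rng.uniform(0.5, 2.0, 8)
        yhat = y + rng.normal(0, 0.1, 8)
        m = calibration_metrics(Identity(), yhat, y, yhat, y)
        rmse = np.sqrt(sum((a - b) ** 2 for a, b in zip(yhat, y)) / 8)
        bias = sum(a - b for a, b in zip(yhat, y)) / 8
        re = 100 * sum(abs(a - b) / b for a, b in zip(yhat, y)) / 8
        assert m.rmsec == pytest.approx(rmse, rel=1e-12)
        assert m.rmsep == pytest.approx(rmse, rel=1e-12)
        assert m.bias == pytest.approx(bias, rel=1e-12)
        assert m.relative_error_pct == pytest.approx(re, rel=1e-12)

    def test_zero_reference_excluded_with_warning(self):
        class Identity:
            def predict(self, X):
                return np.asarray(X, dtype=float).ravel()

        y = np.array([0.0, 1.0, 2.0])
        with pytest.warns(UserWarning, match="zero reference"):
            m = calibration_metrics(Identity(), y + 0.1, y)
        assert m.relative_error_cal_pct == pytest.approx(100 * (0.1 / 1 + 0.1 / 2) / 2)

    def test_no_validation_set_omits_prediction_metrics(self):
        conc = np.array(CALIBRATION_LEVELS)
        fit = LinearCalibration(conc, 10 * conc).fit()
        m = calibration_metrics(fit, 10 * conc, conc)
        assert isinstance(m, CalibrationMetrics)
        assert m.rmsep is None and m.bias is None and m.relative_error_pct is None
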