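"""SIMPLS engine: scaling, fitting, prediction, LOO-CV, and LV selection."""

import numpy as np
import pandas as pd
import pytest

from qsrr import pls


def _fit_autoscaled(X, y, n_lv):
    Xs, ys, params = pls.autoscale(X, y)
    return pls.simpls_fit(Xs, ys, n_lv, scaling=params)


class TestAutoscale:
    def test_two_point_column(self):
        Xs, _, _ = pls.autoscale(np.array([[0.0], [2.0]]))
        assert Xs.ravel() == pytest.approx([-0.7071, 0.7071], abs=1e-4)

    def test_constant_column_named_in_error(self):
        X = pd.DataFrame({"good": [1.0, 2.0, 3.0], "flat": [5.0, 5.0, 5.0]})
        with pytest.raises(ValueError, match="flat"):
            pls.autoscale(X)

    def test_round_trip_identity(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((8, 3))
        y = rng.standard_normal(8)
        Xs, ys, params = pls.autoscale(X, y)
        assert params.unscale_x(Xs) == pytest.approx(X, abs=1e-12)
        assert params.unscale_y(ys) == pytest.approx(y, abs=1e-12)
        assert Xs.mean(axis=0) == pytest.approx(np.zeros(3), abs=1e-12)
        assert Xs.std(axis=0, ddof=1) == pytest.approx(np.ones(3))


class TestSimpls:
    def test_univariate_equals_ols(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((15, 1))
        y = 2.0 * X[:, 0] + rng.standard_normal(15)
        model = _fit_autoscaled(X, y, 1)
        slope, intercept = np.polyfit(X[:, 0], y, 1)
        pred = model.predict(X)
        assert pred == pytest.approx(slope * X[:, 0] + intercept, abs=1e-8)

    def test_full_rank_equals_ols(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((20, 4))
        y = X @ [1.0, -2.0, 0.5, 0.0] + rng.standard_normal(20)
        model = _fit_autoscaled(X, y, 4)
        A = np.column_stack([X, np.ones(20)])
        beta, *_ = np.linalg.lstsq(A, y, rcond=None)
        assert model.predict(X) == pytest.approx(A @ beta, abs=1e-8)

    def test_orthonormal_scores(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((18, 6))
        y = rng.standard_normal(18)
        model = _fit_autoscaled(X, y, 4)
        gram = model.scores.T @ model.scores
        assert gram == pytest.approx(np.eye(4), abs=1e-8)
        assert np.linalg.norm(model.weights, axis=0) == pytest.approx(np.ones(4))

    def test_null_signal_coefficients_near_zero(self):
        # y orthogonal to every column by construction
        X = np.array([[1.0, 0.5], [-1.0, -0.5], [1.0, 0.5], [-1.0, -0.5]])
        y = np.array([1.0, 1.0, -1.0, -1.0])
        model = _fit_autoscaled(X, y, 1)
        assert model.coef_scaled == pytest.approx(np.zeros(2), abs=1e-10)

    def test_explained_variance_properties(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((25, 5))
        y = X @ [1, 1, 0, 0, 0] + 0.1 * rng.standard_normal(25)
        model = _fit_autoscaled(X, y, 5)
        assert np.all(model.explained_y >= -1e-12)
        assert np.all(np.diff(np.cumsum(model.explained_y)) >= -1e-12)
        assert model.explained_x.sum() <= 100 + 1e-9

    def test_matches_sklearn_nipals(self):
        """Independent cross-check: sklearn's NIPALS PLS1 predictions coincide."""
        sklearn_pls = pytest.importorskip("sklearn.cross_decomposition")
        rng = np.random.default_rng(5)
        for n_lv in (1, 2, 3):
            X = rng.standard_normal((16, 6))
            y = X @ rng.standard_normal(6) + 0.3 * rng.standard_normal(16)
            Xs, ys, params = pls.autoscale(X, y)
            model = pls.simpls_fit(Xs, ys, n_lv, scaling=params)
            ref = sklearn_pls.PLSRegression(n_components=n_lv, scale=False).fit(
                Xs, ys
            )
            assert model.predict(X) == pytest.approx(
                params.unscale_y(ref.predict(Xs).ravel()), abs=1e-8
            )

    def test_rank_violation_rejected(self):
        X = np.random.default_rng(6).standard_normal((10, 3))
        Xs, ys, _ = pls.autoscale(X, X @ [1.0, 1.0, 1.0])
        with pytest.raises(ValueError):
            pls.simpls_fit(Xs, ys, 4)


class TestPredict:
    def test_training_reproduction_and_single_row(self, small_xy):
        X, y = small_xy
        model = _fit_autoscaled(X, y, 3)
        full = model.predict(X)
        single = model.predict(X[:1])
        assert single == pytest.approx(full[:1])

    def test_row_permutation_equivariance(self, small_xy):
        X, y = small_xy
        model = _fit_autoscaled(X, y, 2)
        perm = np.random.default_rng(7).permutation(len(y))
        assert model.predict(X[perm]) == pytest.approx(model.predict(X)[perm])

    def test_column_mismatch_rejected(self, small_xy):
        X, y = small_xy
        model = _fit_autoscaled(X, y, 2)
        with pytest.raises(ValueError):
            model.predict(X[:, :3])

    def test_minute_scale_is_exp(self, small_xy):
        X, y = small_xy
        model = _fit_autoscaled(X, y, 2)
        assert model.predict(X, scale="minutes") == pytest.approx(
            np.exp(model.predict(X))
        )


class TestLooCV:
    def test_noiseless_single_descriptor_recovers(self):
        rng = np.random.default_rng(8)
        X = rng.standard_normal((12, 1))
        y = 1.5 * X[:, 0] + 3.0
        cv = pls.loo_cv_curve(X, y, max_lv=1)
        assert cv.rmsecv_ln[0] == pytest.approx(0.0, abs=1e-10)

    def test_against_fold_enumeration_oracle(self):
        """LOO predictions equal a brute-force fold loop with per-fold OLS
        (full-rank SIMPLS) re-estimating the scaling inside each fold."""
        rng = np.random.default_rng(9)
        X = rng.standard_normal((10, 3))
        y = X @ [1.0, 0.5, -0.2] + 0.2 * rng.standard_normal(10)
        preds = pls.loo_predictions(X, y, [3])
        for i in range(10):
            mask = np.arange(10) != i
            A = np.column_stack([X[mask], np.ones(9)])
            beta, *_ = np.linalg.lstsq(A, y[mask], rcond=None)
            assert preds[i, 0] == pytest.approx(
                np.append(X[i], 1.0) @ beta, abs=1e-8
            )

    def test_minimal_size_runs(self):
        X = np.array([[0.0, 1.0], [1.0, 0.0], [2.0, 2.0]])
        y = np.array([0.0, 1.0, 2.0])
        cv = pls.loo_cv_curve(X, y, max_lv=2)
        assert np.all(np.isfinite(cv.rmsecv_ln))

    def test_no_leakage_from_held_out_row(self):
        """Perturbing the held-out response does not move its own prediction."""
        rng = np.random.default_rng(10)
        X = rng.standard_normal((12, 3))
        y = X @ [1.0, -1.0, 0.5] + 0.1 * rng.standard_normal(12)
        base = pls.loo_predictions(X, y, [2])[4, 0]
        y2 = y.copy()
        y2[4] += 100.0
        assert pls.loo_predictions(X, y2, [2])[4, 0] == pytest.approx(base, abs=1e-10)


class TestLVSelection:
    def test_flat_curve_picks_first(self):
        cv = pls.CVResult([1, 2, 3], np.array([2.0, 2.0, 2.0]),
                          np.zeros(3), np.zeros((1, 3)))
        assert pls.select_n_lvs(cv) == 1

    def test_knee_on_elbowed_curve(self):
        cv = pls.CVResult([1, 2, 3, 4], np.array([10.0, 3.0, 2.9, 2.89]),
                          np.zeros(4), np.zeros((1, 4)))
        assert pls.select_n_lvs(cv, policy="knee", tol=0.02) == 2

    def test_min_policy(self):
        cv = pls.CVResult([1, 2, 3], np.array([5.0, 2.0, 3.0]),
                          np.zeros(3), np.zeros((1, 3)))
        assert pls.select_n_lvs(cv, policy="min") == 2


class TestRmse:
    def test_zero_for_exact(self):
        assert pls.rmse([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_hand_value(self):
        assert pls.rmse([3.0, -4.0], [0.0, 0.0]) == pytest.approx(np.sqrt(12.5))

    def test_average(self):
        assert pls.average_rmse(2.0, 4.0) == 3.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            pls.rmse([], [])
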