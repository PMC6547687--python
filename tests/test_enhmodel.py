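"""Preprocessing and cross-validated lasso for enhancer-activity prediction."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from staract import enhmodel as em
from staract import simlib


class TestPreprocess:
    def test_constant_feature_dropped(self, rng):
        X = pd.DataFrame(
            {"const": np.ones(50), "var": rng.normal(size=50)}
        )
        Xn, info = em.preprocess(X)
        assert info.dropped == ["const"]
        assert list(Xn.columns) == ["var"]

    def test_unflagged_normal_feature_only_standardized(self, rng):
        x = rng.normal(size=500)
        X = pd.DataFrame({"f": x})
        Xn, info = em.preprocess(X, skew_flags=pd.Series({"f": False}))
        assert not info.skew_flags["f"]
        expected = (x - x.mean()) / x.std()
        assert np.allclose(Xn["f"], expected)

    def test_log_transform_reduces_skewness(self, rng):
        x = rng.exponential(scale=3.0, size=1000)
        X = pd.DataFrame({"sig": x})
        Xn, _ = em.preprocess(X, skew_flags=pd.Series({"sig": True}))
        assert abs(stats.skew(Xn["sig"])) < abs(stats.skew(x))

    def test_auto_flag_detects_skewed_feature(self, rng):
        X = pd.DataFrame(
            {"skewed": rng.exponential(size=1000), "normal": rng.normal(size=1000)}
        )
        _, info = em.preprocess(X)
        assert info.skew_flags["skewed"]
        assert not info.skew_flags["normal"]

    def test_output_standardized(self, rng):
        X, _, _, flags = simlib.simulate_features(200, 10, 2, seed=3)
        Xn, _ = em.preprocess(X, flags)
        assert np.allclose(Xn.mean(axis=0), 0.0, atol=1e-12)
        assert np.allclose(Xn.std(axis=0, ddof=0), 1.0, atol=1e-12)

    def test_non_finite_input_names_feature(self):
        X = pd.DataFrame({"ok": [1.0, 2.0], "bad": [np.nan, 1.0]})
        with pytest.raises(em.ModelError, match="bad"):
            em.preprocess(X)


class TestFitCv:
    def test_noiseless_recovery_at_vanishing_penalty(self, rng):
        x1 = rng.normal(size=100)
        X = pd.DataFrame(
            {"x1": x1, "x2": rng.normal(size=100), "x3": rng.normal(size=100)}
        )
        y = pd.Series(2.0 * x1)
        model = em.fit_cv(
            X, y, seed=0, nested=False, lambda_grid=[1e-6, 1e-4, 1e-2]
        )
        assert model.coefficients["x1"] == pytest.approx(2.0, abs=5e-3)
        assert abs(model.coefficients[["x2", "x3"]]).max() < 5e-3

    def test_pure_noise_selects_near_empty_model(self, rng):
        X = pd.DataFrame(rng.normal(size=(150, 20)))
        X.columns = [f"f{i}" for i in range(20)]
        y = pd.Series(rng.normal(size=150))
        model = em.fit_cv(X, y, seed=1, nested=False)
        assert model.n_nonzero <= 4
        assert abs(model.rho) < 0.35

    def test_oof_predictions_cover_all_rows_without_leakage(self, rng):
        X, y, _, flags = simlib.simulate_features(120, 15, 3, seed=5)
        Xn, _ = em.preprocess(X, flags)
        model = em.fit_cv(Xn, y, n_folds=10, seed=5, nested=False)
        assert model.oof_predictions.notna().all()
        folds = model.fold_ids
        assert set(folds) == set(range(10))
        sizes = folds.value_counts()
        assert sizes.max() - sizes.min() <= 1
        # out-of-fold predictions differ from in-sample predictions
        in_sample = Xn.to_numpy() @ model.coefficients.to_numpy() + model.intercept
        assert not np.allclose(in_sample, model.oof_predictions)

    def test_column_order_invariance(self, rng):
        X, y, _, flags = simlib.simulate_features(100, 10, 2, seed=8)
        Xn, _ = em.preprocess(X, flags)
        m1 = em.fit_cv(Xn, y, seed=2, nested=False)
        perm = list(Xn.columns[::-1])
        m2 = em.fit_cv(Xn[perm], y, seed=2, nested=False)
        assert m1.lambda_ == pytest.approx(m2.lambda_)
        for c in Xn.columns:
            assert m1.coefficients[c] == pytest.approx(m2.coefficients[c], abs=1e-6)

    def test_sparsity_monotone_in_lambda(self, rng):
        from sklearn.linear_model import Lasso

        X, y, _, flags = simlib.simulate_features(100, 20, 4, seed=9)
        Xn, _ = em.preprocess(X, flags)
        grid = np.logspace(-3, 0.5, 12)
        nnz = [
            (Lasso(alpha=a, max_iter=50_000).fit(Xn, y).coef_ != 0).sum()
            for a in grid
        ]
        assert all(b <= a for a, b in zip(nnz, nnz[1:]))

    def test_degenerate_response_rejected(self, rng):
        X = pd.DataFrame(rng.normal(size=(30, 3)), columns=list("abc"))
        with pytest.raises(em.ModelError):
            em.fit_cv(X, pd.Series(np.ones(30)), n_folds=10)


class TestEvaluate:
    def test_perfect_and_reversed(self, rng):
        y = rng.normal(size=50)
        assert em.evaluate(y, y) == pytest.approx(1.0)
        assert em.evaluate(-y, y) == pytest.approx(-1.0)

    def test_independent_vectors_small_rho(self, rng):
        rhos = [
            em.evaluate(rng.normal(size=100), rng.normal(size=100))
            for _ in range(20)
        ]
        assert np.mean(np.abs(rhos)) < 0.2

    def test_length_mismatch_rejected(self):
        with pytest.raises(em.ModelError):
            em.evaluate([1.0, 2.0], [1.0])


class TestTopCoefficients:
    def _model_with(self, coefs):
        return em.LassoModel(
            lambda_=0.1,
            lambda_grid=np.array([0.1]),
            coefficients=pd.Series(coefs),
            intercept=0.0,
            oof_predictions=pd.Series(dtype=float),
            fold_ids=pd.Series(dtype=int),
            rho=0.0,
            n_folds=10,
            nested=False,
            selection="min",
        )

    def test_fewer_nonzero_than_k(self):
        model = self._model_with({"a": 1.0, "b": 0.0, "c": -2.0, "d": 0.5, "e": 0.0})
        top = em.top_coefficients(model, k=30)
        assert list(top["feature"]) == ["c", "a", "d"]
        assert top["coefficient"].iloc[0] == -2.0  # sign preserved

    def test_k_zero_empty(self):
        model = self._model_with({"a": 1.0})
        assert len(em.top_coefficients(model, k=0)) == 0

    def test_magnitude_tie_broken_by_name(self):
        model = self._model_with({"b": -1.0, "a": 1.0, "c": 2.0})
        top = em.top_coefficients(model, k=3)
        assert list(top["feature"]) == ["c", "a", "b"]
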