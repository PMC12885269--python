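"""Severity estimators: standardization, OLS, SVR LOOCV, stacking, metrics."""

import numpy as np
import pandas as pd
import pytest

import depscore as d
from depscore import models
from depscore.models import (
    LinearSeverityRegressor,
    RankDeficiencyError,
    SVRSeverityRegressor,
    StackingSeverityRegressor,
)


class TestStandardizer:
    def test_hand_computed_column(self):
        std = d.fit_standardizer(np.array([[1.0], [2.0], [3.0]]), ["a"])
        np.testing.assert_allclose(std.transform(np.array([[1.0], [2.0], [3.0]])).ravel(),
                                   [-1.0, 0.0, 1.0])  # sample SD = 1

    def test_train_rows_mean_zero_sd_one(self):
        rng = np.random.default_rng(0)
        X = rng.normal(5, 2, size=(40, 4))
        std = d.fit_standardizer(X)
        Z = std.transform(X)
        np.testing.assert_allclose(Z.mean(axis=0), 0, atol=1e-10)
        np.testing.assert_allclose(Z.std(axis=0, ddof=1), 1, atol=1e-10)

    def test_value_at_train_mean_maps_to_zero(self):
        X = np.array([[2.0], [4.0], [6.0]])
        std = d.fit_standardizer(X)
        assert std.transform(np.array([[4.0]]))[0, 0] == pytest.approx(0.0)

    def test_zero_variance_names_feature(self):
        X = pd.DataFrame({"Q1": [1.0, 2.0, 3.0], "Q2": [5.0, 5.0, 5.0]})
        with pytest.raises(ValueError, match="Q2"):
            d.fit_standardizer(X)


class TestLinearRegressor:
    def test_exact_interpolation(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.normal(size=(30, 2)), columns=["x1", "x2"])
        y = 2 * X["x1"] - X["x2"] + 3
        m = LinearSeverityRegressor().fit(X, y)
        # coefficients are on the z-scored scale: beta_j = raw_j * sd_j
        sd = X.std(ddof=1)
        np.testing.assert_allclose(m.coef_, [2 * sd["x1"], -1 * sd["x2"]], atol=1e-8)
        assert m.intercept_ == pytest.approx(y.mean(), abs=1e-8)
        np.testing.assert_allclose(m.predict(X), y, atol=1e-8)

    def test_constant_outcome(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(20, 3))
        y = np.full(20, 7.0)
        m = LinearSeverityRegressor().fit(X, y)
        np.testing.assert_allclose(m.coef_, 0, atol=1e-10)
        assert m.intercept_ == pytest.approx(7.0)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            n, p = int(rng.integers(10, 40)), int(rng.integers(1, 6))
            X = rng.normal(size=(n, p))
            y = rng.normal(size=n)
            m = LinearSeverityRegressor().fit(X, y)
            Xz = (X - X.mean(0)) / X.std(0, ddof=1)
            A = np.column_stack([np.ones(n), Xz])
            beta = np.linalg.solve(A.T @ A, A.T @ y)
            assert np.max(np.abs(m.coef_ - beta[1:])) <= 1e-8
            assert abs(m.intercept_ - beta[0]) <= 1e-8

    def test_residual_mean_zero_on_train(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(50, 5))
        y = rng.normal(size=50)
        m = LinearSeverityRegressor().fit(X, y)
        assert abs((y - m.predict(X)).mean()) <= 1e-8

    def test_rank_deficiency_lists_collinear_feature(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame({"Q1": rng.normal(size=20)})
        X["Q2"] = rng.normal(size=20)
        X["Q3"] = X["Q1"] * 2.0
        with pytest.raises(RankDeficiencyError) as exc:
            LinearSeverityRegressor().fit(X, rng.normal(size=20))
        assert set(exc.value.collinear) & {"Q1", "Q3"}

    def test_pinv_policy_accepts_duplicates(self):
        rng = np.random.default_rng(6)
        X = pd.DataFrame({"a": rng.normal(size=20)})
        X["b"] = X["a"]
        y = rng.normal(size=20)
        m = LinearSeverityRegressor(rank_deficient="pinv").fit(X, y)
        assert np.isfinite(m.predict(X)).all()

    def test_refuses_mismatched_features(self):
        X = pd.DataFrame(np.random.default_rng(7).normal(size=(20, 2)),
                         columns=["Q1", "Q2"])
        m = LinearSeverityRegressor().fit(X, np.arange(20.0))
        with pytest.raises(ValueError, match="feature mismatch"):
            m.predict(X.rename(columns={"Q2": "Q9"}))

    def test_reordered_dataframe_columns_accepted(self):
        X = pd.DataFrame(np.random.default_rng(8).normal(size=(20, 2)),
                         columns=["Q1", "Q2"])
        m = LinearSeverityRegressor().fit(X, np.arange(20.0))
        np.testing.assert_allclose(m.predict(X[["Q2", "Q1"]]), m.predict(X))

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            LinearSeverityRegressor().fit(np.eye(3), np.arange(3.0))

    def test_clip_option(self):
        X = pd.DataFrame({"x": [0.0, 1.0, 2.0, 3.0]})
        y = np.array([0.0, 10.0, 20.0, 30.0])
        m = LinearSeverityRegressor(clip=True).fit(X, y)
        assert m.predict(pd.DataFrame({"x": [10.0]}))[0] == pytest.approx(24.0)

    def test_sklearn_params_roundtrip(self):
        m = LinearSeverityRegressor(rank_deficient="pinv", clip=True)
        assert LinearSeverityRegressor(**m.get_params()).get_params() == m.get_params()

    def test_category_restriction_never_beats_full_model_in_sample(
            self, small_partitions, depression23):
        X, y = small_partitions["train"]
        full = LinearSeverityRegressor().fit(X, y)
        full_mae = d.evaluate_predictions(y, full.predict(X)).mae
        for cat in depression23.categories():
            qids = [q.qid for q in depression23.by_category(cat)]
            sub = LinearSeverityRegressor().fit(X[qids], y)
            sub_mae = d.evaluate_predictions(y, sub.predict(X[qids])).mae
            assert sub_mae >= full_mae - 1e-9


class TestMetrics:
    def test_perfect_prediction(self):
        m = d.evaluate_predictions([1, 2, 3], [1, 2, 3])
        assert (m.mae, m.rmse, m.r2) == (0.0, 0.0, 1.0)

    def test_hand_arithmetic(self):
        m = d.evaluate_predictions([0.0, 4.0], [2.0, 2.0])
        assert m.mae == pytest.approx(2.0)
        assert m.rmse == pytest.approx(2.0)

    def test_constant_mean_prediction_r2_zero(self):
        y = np.array([1.0, 2.0, 3.0, 6.0])
        m = d.evaluate_predictions(y, np.full(4, y.mean()))
        assert m.r2 == pytest.approx(0.0)

    def test_rmse_at_least_mae(self):
        rng = np.random.default_rng(9)
        y, p = rng.normal(size=30), rng.normal(size=30)
        m = d.evaluate_predictions(y, p)
        assert m.rmse >= m.mae

    def test_single_row_r2_flagged(self):
        assert d.evaluate_predictions([1.0], [2.0]).r2 is None


class TestUnivariate:
    def test_feature_equal_to_outcome(self):
        rng = np.random.default_rng(10)
        y = rng.normal(10, 4, size=60)
        X = pd.DataFrame({"Q1": y})
        rep = d.fit_univariate_models(X, y, B=1000, seed=0)
        assert rep.loc[0, "estimate"] == pytest.approx(np.std(y, ddof=1))
        assert rep.loc[0, "q"] < 0.05

    def test_null_feature_ci_covers_zero(self):
        covered = 0
        for rep_i in range(40):
            rng = np.random.default_rng(100 + rep_i)
            X = pd.DataFrame({"Q1": rng.normal(size=50)})
            y = rng.normal(size=50)
            rep = d.fit_univariate_models(X, y, B=300, seed=rep_i)
            covered += rep.loc[0, "ci_low"] <= 0 <= rep.loc[0, "ci_high"]
        assert covered >= 33  # ~95% coverage, binomial slack

    def test_one_row_per_feature_sorted_by_magnitude(self, small_partitions):
        X, y = small_partitions["train"]
        rep = d.fit_univariate_models(X, y, B=200, seed=1)
        assert len(rep) == 23
        mags = rep["estimate"].abs().to_numpy()
        assert (np.diff(mags) <= 1e-12).all()


class TestSVR:
    def test_single_value_grid_selected(self, small_partitions):
        X, y = small_partitions["train"]
        m = SVRSeverityRegressor(C_grid=[2.0]).fit(X.iloc[:15, :3], y[:15])
        assert m.C_ == 2.0

    def test_selection_reproducible(self, small_partitions):
        X, y = small_partitions["train"]
        grid = [0.5, 4.0]
        m1 = SVRSeverityRegressor(C_grid=grid).fit(X.iloc[:15, :3], y[:15])
        m2 = SVRSeverityRegressor(C_grid=grid).fit(X.iloc[:15, :3], y[:15])
        assert m1.C_ == m2.C_ and m1.loocv_mae_ == m2.loocv_mae_

    def test_loocv_fold_independent_of_held_out_label(self, small_partitions):
        from depscore.models import _loocv_predictions
        X, y = small_partitions["train"]
        Xs = X.iloc[:12, :3].to_numpy()
        ys = y[:12].copy()

        def fp(Xtr, ytr, xrow):
            return float(LinearSeverityRegressor().fit(Xtr, ytr).predict(xrow)[0])

        base = _loocv_predictions(fp, Xs, ys)
        ys2 = ys.copy()
        ys2[5] += 100.0
        perturbed = _loocv_predictions(fp, Xs, ys2)
        assert perturbed[5] == pytest.approx(base[5], abs=1e-9)

    def test_degenerate_grid_rejected(self, small_partitions):
        X, y = small_partitions["train"]
        with pytest.raises(ValueError):
            SVRSeverityRegressor(C_grid=[]).fit(X.iloc[:10, :2], y[:10])


class TestStacking:
    def _cats(self, depression23):
        return {c: [q.qid for q in depression23.by_category(c)]
                for c in depression23.categories()}

    def test_meta_design_shape(self, small_partitions, depression23):
        X, y = small_partitions["train"]
        m = StackingSeverityRegressor(categories=self._cats(depression23)).fit(X, y)
        assert m.oof_meta_design_.shape == (len(y), 3)

    def test_perfect_base_model_dominates(self):
        rng = np.random.default_rng(11)
        n = 40
        X = pd.DataFrame({
            "a1": rng.normal(size=n), "a2": rng.normal(size=n),
            "b1": rng.normal(size=n),
        })
        y = (3 * X["a1"] + X["a2"]).to_numpy()  # category A predicts exactly
        cats = {"A": ["a1", "a2"], "B": ["b1"]}
        m = StackingSeverityRegressor(categories=cats).fit(X, y)
        Xt = pd.DataFrame({
            "a1": rng.normal(size=20), "a2": rng.normal(size=20),
            "b1": rng.normal(size=20),
        })
        yt = (3 * Xt["a1"] + Xt["a2"]).to_numpy()
        base_mae = d.evaluate_predictions(
            yt, m.base_models_["A"].predict(Xt[["a1", "a2"]])).mae
        stack_mae = d.evaluate_predictions(yt, m.predict(Xt)).mae
        assert stack_mae <= base_mae + 1e-6

    def test_requires_two_categories(self, small_partitions):
        X, y = small_partitions["train"]
        with pytest.raises(ValueError):
            StackingSeverityRegressor(categories={"only": ["Q1"]}).fit(X, y)

    def test_empty_category_rejected(self, small_partitions):
        X, y = small_partitions["train"]
        with pytest.raises(ValueError, match="no features"):
            StackingSeverityRegressor(categories={"a": ["Q1"], "b": []}).fit(X, y)


class TestPersistence:
    def test_ols_roundtrip(self, tmp_path, small_partitions):
        X, y = small_partitions["train"]
        m = LinearSeverityRegressor().fit(X, y)
        models.save_model(m, tmp_path / "m.json")
        back = models.load_model(tmp_path / "m.json")
        np.testing.assert_allclose(back.predict(X), m.predict(X))

    def test_svr_roundtrip(self, tmp_path, small_partitions):
        X, y = small_partitions["train"]
        m = SVRSeverityRegressor(C_grid=[1.0]).fit(X.iloc[:, :4], y)
        models.save_model(m, tmp_path / "m.json")
        back = models.load_model(tmp_path / "m.json")
        np.testing.assert_allclose(back.predict(X.iloc[:, :4]), m.predict(X.iloc[:, :4]),
                                   atol=1e-8)

    def test_stacking_roundtrip(self, tmp_path, small_partitions, depression23):
        X, y = small_partitions["train"]
        cats = {c: [q.qid for q in depression23.by_category(c)]
                for c in depression23.categories()}
        m = StackingSeverityRegressor(categories=cats).fit(X, y)
        models.save_model(m, tmp_path / "m.json")
        back = models.load_model(tmp_path / "m.json")
        np.testing.assert_allclose(back.predict(X), m.predict(X))
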