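"""Median split, t filter, alias/VIF removal, and the LASSO solver."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.linear_model import Lasso as SkLasso

from radtiles.selection import (
    drop_aliased,
    kkt_residual,
    lasso_fit,
    lasso_path_fit,
    median_split,
    predict_tiles,
    published_model,
    run_selection_pipeline,
    TilesLasso,
    ttest_filter,
    vif_filter,
    _standardize,
)
from radtiles.simulate import simulate_feature_matrix


class TestMedianSplit:
    def test_median_value_goes_high(self):
        high = median_split([1.0, 2.0, 3.0])
        np.testing.assert_array_equal(high, [False, True, True])

    def test_even_count_no_median_tie(self):
        high = median_split([1.0, 1.0, 2.0, 2.0])
        np.testing.assert_array_equal(high, [False, False, True, True])

    def test_all_equal_degenerate_all_high(self):
        assert median_split([5.0, 5.0, 5.0]).all()

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=31)
        np.testing.assert_array_equal(median_split(v), median_split(np.exp(v)))


class TestTTestFilter:
    def test_separated_groups_retained(self):
        # feature splits y into {0.1,0.2,0.3} vs {1.1,1.2,1.3}
        X = pd.DataFrame({"f": [0, 0, 0, 1, 1, 1]})
        y = np.array([0.1, 0.2, 0.3, 1.1, 1.2, 1.3])
        rep = ttest_filter(X, y)
        t_expected, _ = stats.ttest_ind(y[:3], y[3:], equal_var=True)
        assert rep.loc["f", "t_stat"] == pytest.approx(t_expected)
        assert rep.loc["f", "t_stat"] == pytest.approx(-12.24744871, rel=1e-8)
        assert rep.loc["f", "retained"]

    def test_identical_groups_removed(self):
        X = pd.DataFrame({"f": [0, 0, 1, 1] * 5})
        y = np.array([0.5, 0.6] * 10)
        rep = ttest_filter(X, y)
        assert not rep.loc["f", "retained"]
        assert rep.loc["f", "p_value"] > 0.5

    def test_cutoff_is_strict(self):
        X = pd.DataFrame({"f": [0, 0, 0, 1, 1, 1]})
        y = np.array([0.1, 0.2, 0.3, 1.1, 1.2, 1.3])
        p = ttest_filter(X, y).loc["f", "p_value"]
        rep = ttest_filter(X, y, alpha=p)  # p < p is false
        assert not rep.loc["f", "retained"]

    def test_degenerate_split_noted(self):
        X = pd.DataFrame({"f": [3.0] * 10})
        y = np.arange(10.0)
        rep = ttest_filter(X, y)
        assert rep.loc["f", "note"] == "degenerate split"


class TestAliasAndVif:
    def test_duplicate_column_dropped(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=20)
        X = pd.DataFrame({"a": a, "b": rng.normal(size=20), "a2": a})
        kept, dropped = drop_aliased(X)
        assert dropped == ["a2"] and list(kept.columns) == ["a", "b"]

    def test_linear_combination_dropped(self):
        rng = np.random.default_rng(2)
        A, B = rng.normal(size=5), rng.normal(size=5)
        X = pd.DataFrame({"A": A, "B": B, "C": 2 * A + 3 * B})
        kept, dropped = drop_aliased(X)
        assert dropped == ["C"]
        assert np.linalg.matrix_rank(X.to_numpy()) == 2  # rank oracle

    def test_constant_column_is_aliased(self):
        X = pd.DataFrame({"c": np.ones(10), "a": np.arange(10.0)})
        _, dropped = drop_aliased(X)
        assert dropped == ["c"]

    def test_full_rank_unchanged(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.normal(size=(30, 5)), columns=list("abcde"))
        kept, dropped = drop_aliased(X)
        assert dropped == [] and kept.shape == (30, 5)

    def test_orthogonal_columns_vif_one(self):
        X = pd.DataFrame(np.eye(6)[:, :3], columns=list("abc"))
        kept, dropped = vif_filter(X)
        assert dropped == []

    def test_near_collinear_removed_first(self):
        rng = np.random.default_rng(4)
        x1, x2 = rng.normal(size=50), rng.normal(size=50)
        x3 = x1 + x2 + rng.normal(0, 1e-3, 50)
        X = pd.DataFrame({"x1": x1, "x2": x2, "x3": x3})
        kept, dropped = vif_filter(X)
        assert dropped == ["x3"]

    def test_cutoff_is_strict(self):
        rng = np.random.default_rng(5)
        x1 = rng.normal(size=100)
        x2 = 0.9 * x1 + rng.normal(0, 0.5, 100)
        X = pd.DataFrame({"x1": x1, "x2": x2})
        from radtiles.selection import _vif_values

        vmax = _vif_values(X.to_numpy()).max()
        _, dropped = vif_filter(X, cutoff=vmax)  # "more than" is strict
        assert dropped == []


class TestLasso:
    def _problem(self, seed=0, n=80, p=6):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame(rng.normal(size=(n, p)), columns=[f"f{i}" for i in range(p)])
        beta = np.zeros(p)
        beta[:2] = [1.5, -2.0]
        y = X.to_numpy() @ beta + rng.normal(0, 0.3, n)
        return X, y

    def test_all_zero_at_lambda_max(self):
        X, y = self._problem()
        lam_grid, betas, _ = lasso_path_fit(X, y)
        assert np.allclose(betas[0], 0.0)
        # and strictly above lambda_max too
        lam2 = np.array([lam_grid[0] * 2.0])
        _, b2, _ = lasso_path_fit(X, y, lambda_grid=lam2)
        assert np.allclose(b2, 0.0)

    def test_lambda_zero_equals_least_squares(self):
        X, y = self._problem()
        _, betas, info = lasso_path_fit(X, y, lambda_grid=np.array([0.0]))
        Xs, _, _ = _standardize(X.to_numpy())
        ols = np.linalg.lstsq(Xs, y - y.mean(), rcond=None)[0]
        assert np.allclose(betas[0], ols, atol=1e-6)

    def test_orthonormal_design_soft_threshold(self):
        rng = np.random.default_rng(7)
        n, p = 64, 4
        A = rng.normal(size=(n, p))
        A -= A.mean(axis=0)  # center before QR so Q stays exactly orthogonal
        Q, _ = np.linalg.qr(A)
        Xs = Q / Q.std(axis=0)  # unit 1/N-variance, orthogonal columns
        y = rng.normal(size=n)
        lam = 0.1
        X = pd.DataFrame(Xs, columns=list("abcd"))
        _, betas, _ = lasso_path_fit(X, y, lambda_grid=np.array([lam]))
        yc = y - y.mean()
        rho = Xs.T @ yc / n
        expected = np.sign(rho) * np.maximum(np.abs(rho) - lam, 0.0)
        assert np.allclose(betas[0], expected, atol=1e-8)

    def test_kkt_residual_small(self):
        for seed in range(3):
            X, y = self._problem(seed)
            model = lasso_fit(X, y, cv_folds=5, seed=seed)
            assert model.diagnostics["kkt_residual"] < 1e-6

    def test_agrees_with_sklearn(self):
        X, y = self._problem(9)
        Xs, _, _ = _standardize(X.to_numpy())
        yc = y - y.mean()
        lam = 0.05
        _, betas, _ = lasso_path_fit(X, y, lambda_grid=np.array([lam]))
        sk = SkLasso(alpha=lam, fit_intercept=False, tol=1e-12, max_iter=100000)
        sk.fit(Xs, yc)
        assert np.allclose(betas[0], sk.coef_, atol=1e-6)

    def test_objective_decreases_along_warm_start_path(self):
        from radtiles.selection import _objective

        X, y = self._problem(11)
        lam_grid, betas, _ = lasso_path_fit(X, y)
        Xs, _, _ = _standardize(X.to_numpy())
        yc = y - y.mean()
        # at fixed lambda the solution beats the zero vector and the KKT
        # check holds everywhere along the path
        for k in (10, 50, 99):
            lam = float(lam_grid[k])
            assert _objective(Xs, yc, betas[k], lam, 1.0) <= _objective(
                Xs, yc, np.zeros(Xs.shape[1]), lam, 1.0
            )
            assert kkt_residual(Xs, yc, betas[k], lam, 1.0) < 1e-6

    def test_prediction_standardization_round_trip(self):
        X, y = self._problem(13)
        model = lasso_fit(X, y, cv_folds=5, seed=1)
        # original-scale evaluation vs standardized-scale evaluation
        direct = model.predict(X).to_numpy()
        mu = np.array([model.standardization[c][0] for c in X.columns])
        sd = np.array([model.standardization[c][1] for c in X.columns])
        beta_std = np.array([model.coefficients[c] for c in X.columns]) * sd
        via_std = (X.to_numpy() - mu) / sd @ beta_std + (
            model.intercept + mu @ np.array([model.coefficients[c] for c in X.columns])
        )
        assert np.allclose(direct, via_std, atol=1e-10)


class TestPipeline:
    def test_causal_features_recovered(self):
        df = simulate_feature_matrix(220, seed=0)
        model, report = run_selection_pipeline(
            df.drop(columns="tiles"), df["tiles"].to_numpy(), seed=0
        )
        assert model is not None
        assert model.coefficients["glszm_GrayLevelVariance"] > 0
        assert model.coefficients["glszm_LargeAreaLowGrayLevelEmphasis"] < 0
        assert set(report["stage"]) <= {"t_filter", "alias", "vif", "lasso_zero", "kept"}
        assert len(report) == 88  # every feature accounted for

    def test_null_response_selects_almost_nothing(self):
        rng = np.random.default_rng(21)
        df = simulate_feature_matrix(120, seed=21)
        y = rng.uniform(0, 1, 120)  # independent of all features
        rep = ttest_filter(df.drop(columns="tiles"), y)
        assert rep["retained"].sum() <= 4  # expect ~0.44 of 88 at p<0.005

    def test_single_causal_feature_survives_all_stages(self):
        rng = np.random.default_rng(31)
        n = 150
        h = rng.uniform(size=n)
        X = pd.DataFrame(rng.normal(size=(n, 10)), columns=[f"n{i}" for i in range(10)])
        X["causal"] = 10 * h + rng.normal(0, 1, n)
        y = h + rng.normal(0, 0.05, n)
        model, report = run_selection_pipeline(X, y, seed=31)
        assert report.loc["causal", "stage"] == "kept"
        assert model.coefficients["causal"] > 0

    def test_empty_model_not_exception(self):
        rng = np.random.default_rng(41)
        X = pd.DataFrame(rng.normal(size=(60, 5)), columns=list("abcde"))
        y = rng.uniform(size=60)
        model, report = run_selection_pipeline(X, y, seed=41)
        if model is None:
            assert (report["stage"] == "t_filter").all()

    def test_results_object_summary(self):
        df = simulate_feature_matrix(150, seed=2)
        res = TilesLasso.from_dataframe(df).fit(seed=2)
        text = res.summary()
        assert "lambda" in text and "intercept" in text
        assert res.params.index[0] == "intercept"
        fc = res.log2_fold_changes()
        assert {"log2fc_mean", "log2fc_median"} <= set(fc.columns)


class TestPublishedModel:
    def test_worked_score_arithmetic(self):
        m = published_model()
        X = pd.DataFrame(
            {
                "glszm_GrayLevelVariance": [100.0],
                "glszm_LargeAreaLowGrayLevelEmphasis": [10000.0],
            }
        )
        assert m.predict(X).iloc[0] == pytest.approx(-0.077)
        assert not m.intercept_known

    def test_all_zero_features_score_zero(self):
        m = published_model()
        X = pd.DataFrame(
            {"glszm_GrayLevelVariance": [0.0], "glszm_LargeAreaLowGrayLevelEmphasis": [0.0]}
        )
        assert m.predict(X).iloc[0] == 0.0

    def test_score_increases_with_glv(self):
        m = published_model()
        X = pd.DataFrame(
            {
                "glszm_GrayLevelVariance": [100.0, 200.0],
                "glszm_LargeAreaLowGrayLevelEmphasis": [5000.0, 5000.0],
            }
        )
        s = m.predict(X)
        assert s.iloc[1] > s.iloc[0]

    def test_missing_feature_named(self):
        m = published_model()
        X = pd.DataFrame({"glszm_GrayLevelVariance": [1.0]})
        with pytest.raises(KeyError, match="LargeAreaLowGrayLevelEmphasis"):
            m.predict(X)

    def test_median_grouping_ties_high(self):
        m = published_model()
        X = pd.DataFrame(
            {
                "glszm_GrayLevelVariance": [100.0, 200.0, 300.0],
                "glszm_LargeAreaLowGrayLevelEmphasis": [0.0, 0.0, 0.0],
            }
        )
        out = predict_tiles(X, m)
        assert list(out["tiles_group"]) == ["low", "high", "high"]
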