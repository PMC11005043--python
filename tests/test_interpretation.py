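from math import comb

import numpy as np
import pandas as pd
import pytest

from enzymd import interpretation as itp
from enzymd import model_bench as mb


from sklearn.base import BaseEstimator, RegressorMixin


class _OracleModel(BaseEstimator, RegressorMixin):
    """Deterministic estimator whose prediction is an exact function of a
    single feature."""

    def __init__(self, col=0):
        self.col = col

    def fit(self, X, y):
        return self

    def predict(self, X):
        return np.asarray(X)[:, self.col] * 2.0


class TestPermutationImportance:
    def test_constant_feature_zero_importance(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame({"a": rng.standard_normal(60),
                          "const": np.ones(60)})
        y = X["a"].to_numpy() * 2.0
        imp = itp.permutation_importance(_OracleModel(), X, y, seed=0)
        assert imp.loc["const", "importance"] == pytest.approx(0.0, abs=1e-12)

    def test_oracle_single_feature_model(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.standard_normal((80, 4)),
                         columns=list("abcd"))
        y = X["a"].to_numpy() * 2.0
        imp = itp.permutation_importance(_OracleModel(0), X, y, seed=0)
        assert imp.index[0] == "a"
        assert imp.loc["a", "importance"] > 0.5
        for other in "bcd":
            assert imp.loc[other, "importance"] == pytest.approx(0.0,
                                                                 abs=1e-12)

    def test_duplicated_column_shares_importance(self):
        rng = np.random.default_rng(2)
        base = rng.standard_normal(200)
        y = 2.0 * base
        X_solo = pd.DataFrame({"a": base, "noise": rng.standard_normal(200)})
        model = mb.make_boosted_tree(seed=0, n_estimators=50)
        model.fit(X_solo, y)
        solo = itp.permutation_importance(model, X_solo, y, seed=0)
        X_dup = pd.DataFrame({"a": base, "a2": base,
                              "noise": X_solo["noise"]})
        model2 = mb.make_boosted_tree(seed=0, n_estimators=50)
        model2.fit(X_dup, y)
        dup = itp.permutation_importance(model2, X_dup, y, seed=0)
        tol = 1e-6
        assert dup.loc["a", "importance"] <= solo.loc["a", "importance"] + tol
        assert dup.loc["a2", "importance"] <= solo.loc["a", "importance"] + tol

    def test_unknown_metric_rejected(self):
        with pytest.raises(ValueError):
            itp.permutation_importance(_OracleModel(), pd.DataFrame({"a": [1.0]}),
                                       [1.0], metric="accuracy")


class TestTreeImportances:
    def test_stump_concentrates_on_driving_feature(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.standard_normal((200, 4)),
                         columns=["f1", "f2", "f3", "f4"])
        y = (X["f3"] > 0).astype(float).to_numpy() * 5.0
        model = mb.make_boosted_tree(seed=0, n_estimators=1, num_leaves=2,
                                     min_child_samples=5)
        model.fit(X, y)
        ranks = itp.tree_importances(model)
        assert ranks["gain"].index[0] == "f3"
        assert ranks["split"]["f3"] == 1
        assert (ranks["split"].drop("f3") == 0).all()
        assert len(ranks["gain"]) == 4

    def test_unfitted_model_rejected(self):
        with pytest.raises(ValueError):
            itp.tree_importances(mb.make_boosted_tree())


class TestExactShapley:
    def test_additive_model_closed_form(self):
        def predict(X):
            X = np.atleast_2d(X)
            return X[:, 0] + 3.0 * X[:, 1]

        background = np.array([[1.0, 2.0], [3.0, 4.0]])
        x = np.array([10.0, 10.0])
        phi = itp.shapley_exact_small(predict, x, background)
        # additive: phi_j = coefficient * (x_j - background mean_j)
        assert phi[0] == pytest.approx(10.0 - 2.0, abs=1e-10)
        assert phi[1] == pytest.approx(3.0 * (10.0 - 3.0), abs=1e-10)

    def test_symmetric_features_equal_values(self):
        def predict(X):
            X = np.atleast_2d(X)
            return X[:, 0] * X[:, 1]

        phi = itp.shapley_exact_small(predict, np.array([2.0, 2.0]),
                                      np.zeros((1, 2)))
        assert phi[0] == pytest.approx(phi[1], abs=1e-10)

    def test_local_accuracy(self):
        rng = np.random.default_rng(4)
        X_bg = rng.standard_normal((7, 6))

        def predict(X):
            X = np.atleast_2d(X)
            return np.sin(X[:, 0]) + X[:, 1] * X[:, 2] - np.abs(X[:, 3])

        for _ in range(5):
            x = rng.standard_normal(6)
            phi = itp.shapley_exact_small(predict, x, X_bg)
            expect = predict(x[None])[0] - predict(X_bg).mean()
            assert phi.sum() == pytest.approx(expect, abs=1e-10)

    def test_feature_limit_enforced(self):
        with pytest.raises(ValueError, match="max_features"):
            itp.shapley_exact_small(lambda X: np.zeros(len(np.atleast_2d(X))),
                                    np.zeros(13), np.zeros((1, 13)))


class TestShapSummary:
    def test_constant_model_zero_attributions(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame(rng.standard_normal((50, 3)), columns=list("abc"))
        model = mb.make_boosted_tree(seed=0, n_estimators=5)
        model.fit(X, np.ones(50))
        res = itp.shap_summary(model, X)
        np.testing.assert_allclose(res["values"].to_numpy(), 0.0, atol=1e-12)

    def test_stump_attributes_to_single_feature(self):
        rng = np.random.default_rng(6)
        X = pd.DataFrame(rng.standard_normal((200, 3)), columns=list("abc"))
        y = (X["b"] > 0).to_numpy() * 4.0
        model = mb.make_boosted_tree(seed=0, n_estimators=1, num_leaves=2)
        model.fit(X, y)
        res = itp.shap_summary(model, X)
        assert res["ranking"].index[0] == "b"
        np.testing.assert_allclose(res["values"][["a", "c"]].to_numpy(), 0.0,
                                   atol=1e-12)

    def test_depth_one_ensemble_matches_exact_shapley(self):
        """An additive (stump) ensemble's tree-path attributions equal the
        exact interventional Shapley values with the training set as
        background."""
        rng = np.random.default_rng(7)
        X = pd.DataFrame(rng.standard_normal((80, 6)),
                         columns=[f"f{i}" for i in range(6)])
        y = X["f0"].to_numpy() - 2.0 * (X["f3"] > 0.3) + 0.5 * X["f5"].to_numpy()
        model = mb.make_boosted_tree(seed=0, n_estimators=40, num_leaves=2,
                                     learning_rate=0.3)
        model.fit(X, y)
        res = itp.shap_summary(model, X)
        bg = X.to_numpy()
        for row in (0, 17, 42):
            phi = itp.shapley_exact_small(model.predict, bg[row], bg)
            np.testing.assert_allclose(res["values"].iloc[row].to_numpy(),
                                       phi, atol=1e-6)

    def test_non_tree_model_rejected(self):
        from sklearn.linear_model import Ridge

        with pytest.raises(ValueError, match="LightGBM"):
            itp.shap_summary(Ridge().fit(np.eye(3), np.arange(3)),
                             pd.DataFrame(np.eye(3)))

    def test_interaction_strength_ranking(self):
        rng = np.random.default_rng(8)
        X = pd.DataFrame(rng.standard_normal((300, 3)),
                         columns=["x", "partner", "noise"])
        y = (X["x"] * X["partner"]).to_numpy()
        model = mb.make_boosted_tree(seed=0, n_estimators=200, num_leaves=7)
        model.fit(X, y)
        res = itp.shap_summary(model, X)
        assert res["interaction_strength"]("x").index[0] == "partner"


class TestErrorLabels:
    def test_counts_follow_quantile_convention(self):
        rng = np.random.default_rng(9)
        y = rng.standard_normal(100)
        yhat = y + rng.standard_normal(100)
        labels, lo, hi = itp.error_threshold_labels(y, yhat)
        resid = yhat - y
        assert (labels == "poor_low").sum() == (resid < np.quantile(resid, 0.05)).sum()
        assert (labels == "poor_high").sum() == (resid > np.quantile(resid, 0.95)).sum()
        assert set(labels) <= {"poor_low", "ok", "poor_high"}
        assert lo < hi

    def test_identical_residuals_no_poor_labels(self):
        y = np.zeros(30)
        yhat = np.full(30, 0.7)
        labels, lo, hi = itp.error_threshold_labels(y, yhat)
        assert (labels == "ok").all()
        assert lo == hi

    def test_too_few_cases_rejected(self):
        with pytest.raises(ValueError):
            itp.error_threshold_labels(np.zeros(10), np.zeros(10))


class TestHypergeometric:
    def test_everything_flagged_gives_p_one(self):
        labels = np.array(["poor_high"] * 3 + ["ok"] * 7)
        res = itp.hypergeometric_enrichment(labels, np.ones(10, dtype=bool))
        assert res.k == res.s == 3
        assert res.p_value == pytest.approx(1.0)

    def test_known_exact_value(self):
        # N=10, K=5, s=4, k=4 -> C(5,4)/C(10,4) = 5/210
        labels = np.array(["poor_low"] * 4 + ["ok"] * 6)
        flags = np.array([True] * 4 + [False] * 5 + [True])
        res = itp.hypergeometric_enrichment(labels, flags)
        assert (res.N, res.K, res.s, res.k) == (10, 5, 4, 4)
        assert res.p_value == pytest.approx(5 / 210, abs=1e-12)
        assert res.fold == pytest.approx((4 / 4) / (5 / 10))

    def test_matches_enumeration_all_small_populations(self):
        from scipy.stats import hypergeom

        for N in range(1, 13):
            for K in range(N + 1):
                for s in range(N + 1):
                    for k in range(max(0, s + K - N), min(s, K) + 1):
                        exact = sum(
                            comb(K, j) * comb(N - K, s - j)
                            for j in range(k, min(s, K) + 1)
                        ) / comb(N, s)
                        p = float(hypergeom.sf(k - 1, N, K, s))
                        assert p == pytest.approx(exact, abs=1e-12), (N, K, s, k)

    def test_no_poor_predictions_degenerate(self):
        labels = np.array(["ok"] * 25)
        res = itp.hypergeometric_enrichment(labels,
                                            np.zeros(25, dtype=bool))
        assert res.p_value == 1.0 and np.isnan(res.fold)
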