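"""Additive attributions: local accuracy, Shapley oracles, analytics."""

import numpy as np
import pandas as pd
import pytest
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import GaussianNB
from xgboost import DMatrix, XGBClassifier

from relifex import (
    ClassifierSpec,
    cluster_explanations,
    compute_attributions,
    correlation_network,
    dependence_profile,
    global_importance,
    marginal_importance_curve,
    tune_and_evaluate,
)
from relifex.attribution import AttributionMatrix, model_margin
from oracles import (
    interventional_value_function,
    shapley_brute_force,
    tree_value_function,
)


@pytest.fixture(scope="module")
def small_tree_model():
    rng = np.random.default_rng(3)
    X = pd.DataFrame(rng.normal(size=(120, 3)), columns=["f0", "f1", "f2"])
    y = (X.f0 + 0.8 * X.f1 + rng.normal(0, 0.4, 120) > 0).astype(int)
    model = XGBClassifier(
        n_estimators=6, max_depth=2, tree_method="hist",
        eval_metric="logloss", random_state=0,
    ).fit(X.to_numpy(), y)
    return model, X, y


class TestTreeBackend:
    def test_local_accuracy_within_exact_tolerance(self, fitted_gbt):
        model, X, y = fitted_gbt
        attr = compute_attributions(model, X)
        assert attr.method == "tree"
        assert attr.local_accuracy_residual().max() <= 1e-6

    def test_agrees_with_booster_native_contributions(self, fitted_gbt):
        # the booster's own float32 path attributions are an independent
        # implementation of the same tree value function
        model, X, y = fitted_gbt
        attr = compute_attributions(model, X)
        contribs = model.get_booster().predict(DMatrix(X), pred_contribs=True)
        assert np.abs(attr.phi.to_numpy() - contribs[:, :-1]).max() < 1e-4
        assert attr.phi0 == pytest.approx(float(contribs[0, -1]), abs=1e-4)
        margin = model.get_booster().predict(DMatrix(X), output_margin=True)
        assert np.abs(attr.predictions - margin).max() < 1e-4

    def test_matches_coalition_enumeration_oracle(self, small_tree_model):
        model, X, y = small_tree_model
        attr = compute_attributions(model, pd.DataFrame(X.to_numpy()))
        booster = model.get_booster()
        for i in range(8):  # a handful of instances is plenty
            x = X.iloc[i].to_numpy()
            # constant offsets cancel in Shapley differences; pass 0
            phi_oracle = shapley_brute_force(
                lambda S: tree_value_function(booster, x, S, 0.0), 3
            )
            assert np.allclose(attr.phi.iloc[i].to_numpy(), phi_oracle,
                               atol=1e-9)

    def test_unused_feature_gets_zero_attribution(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame({"used": rng.normal(size=150),
                          "dummy": rng.normal(size=150)})
        y = (X.used > 0).astype(int)
        model = XGBClassifier(
            n_estimators=10, max_depth=1, tree_method="hist",
            eval_metric="logloss", random_state=0,
        ).fit(X, y)
        attr = compute_attributions(model, X)
        assert np.all(attr.phi["dummy"].to_numpy() == 0.0)

    def test_feature_mismatch_rejected(self, fitted_gbt):
        model, X, y = fitted_gbt
        wrong = X.rename(columns={X.columns[0]: "renamed"})
        with pytest.raises(ValueError, match="feature set"):
            compute_attributions(model, wrong)


class TestLinearBackend:
    def test_matches_interventional_oracle(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.normal(size=(60, 4)),
                         columns=[f"f{i}" for i in range(4)])
        y = (X.f0 - X.f1 + rng.normal(0, 0.5, 60) > 0).astype(int)
        model = LogisticRegression(max_iter=1000).fit(X, y)
        bg = X.iloc[:16]
        attr = compute_attributions(model, X, background=bg)
        assert attr.method == "linear"

        def margin_fn(arr):
            return model.decision_function(
                pd.DataFrame(arr, columns=X.columns)
            )

        for i in (0, 7, 33):
            x = X.iloc[i].to_numpy()
            phi_oracle = shapley_brute_force(
                lambda S: interventional_value_function(
                    margin_fn, x, bg.to_numpy().copy(), S
                ),
                4,
            )
            assert np.allclose(attr.phi.iloc[i].to_numpy(), phi_oracle,
                               atol=1e-8)
        assert attr.local_accuracy_residual().max() <= 1e-8

    def test_symmetric_features_get_equal_attribution(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.normal(size=(80, 2)), columns=["a", "b"])
        y = (X.a + X.b > 0).astype(int)
        model = LogisticRegression(max_iter=1000).fit(X, y)
        # symmetry axiom needs model AND value function symmetric in (a, b):
        # equal coefficients plus a background symmetric in the two columns
        w = model.coef_.mean()
        model.coef_ = np.array([[w, w]])
        bg = pd.concat(
            [X, X.rename(columns={"a": "b", "b": "a"})[["a", "b"]]],
            ignore_index=True,
        )
        pt = pd.DataFrame({"a": [1.3], "b": [1.3]})
        attr = compute_attributions(model, pt, background=bg)
        assert attr.phi.iloc[0, 0] == pytest.approx(attr.phi.iloc[0, 1])


class TestSamplingBackend:
    def test_exhaustive_small_model_matches_oracle(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame(rng.normal(size=(40, 3)), columns=["a", "b", "c"])
        y = (X.a + 0.5 * X.b > 0).astype(int)
        model = GaussianNB().fit(X, y)
        bg = X.iloc[:12]
        attr = compute_attributions(model, X.iloc[:10], background=bg,
                                    method="sampling")
        assert "exhaustive" in attr.background

        def margin_fn(arr):
            return model_margin(model, pd.DataFrame(arr, columns=X.columns))

        for i in range(5):
            x = X.iloc[i].to_numpy()
            phi_oracle = shapley_brute_force(
                lambda S: interventional_value_function(
                    margin_fn, x, bg.to_numpy().copy(), S
                ),
                3,
            )
            assert np.allclose(attr.phi.iloc[i].to_numpy(), phi_oracle,
                               atol=1e-8)

    def test_local_accuracy_exact_even_when_sampled(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame(rng.normal(size=(30, 7)),
                         columns=[f"f{i}" for i in range(7)])
        y = (X.sum(axis=1) > 0).astype(int)
        model = GaussianNB().fit(X, y)
        attr = compute_attributions(model, X.iloc[:6], background=X.iloc[:20],
                                    method="sampling", n_permutations=8, seed=0)
        assert attr.local_accuracy_residual().max() <= 1e-9


class TestGlobalImportance:
    def test_forced_arithmetic(self):
        attr = AttributionMatrix(
            phi=pd.DataFrame([[1.0, -2.0], [-3.0, 0.0]], columns=["a", "b"]),
            phi0=0.0, predictions=np.zeros(2), method="tree",
            tolerance=1e-6, background="",
        )
        ranking = global_importance(attr)
        assert ranking.table["importance"].tolist() == [2.0, 1.0]
        assert ranking.ranked_features == ["a", "b"]

    def test_zero_column_ranked_last_and_sign_invariance(self):
        rng = np.random.default_rng(0)
        phi = pd.DataFrame(rng.normal(size=(20, 3)), columns=["a", "b", "z"])
        phi["z"] = 0.0
        attr = AttributionMatrix(phi, 0.0, np.zeros(20), "tree", 1e-6, "")
        ranking = global_importance(attr)
        assert ranking.ranked_features[-1] == "z"
        flipped = AttributionMatrix(-phi, 0.0, np.zeros(20), "tree", 1e-6, "")
        assert global_importance(flipped).ranked_features == \
            ranking.ranked_features

    def test_instance_order_invariance(self):
        rng = np.random.default_rng(1)
        phi = pd.DataFrame(rng.normal(size=(15, 4)))
        attr = AttributionMatrix(phi, 0.0, np.zeros(15), "tree", 1e-6, "")
        shuffled = AttributionMatrix(
            phi.sample(frac=1, random_state=2).reset_index(drop=True),
            0.0, np.zeros(15), "tree", 1e-6, "",
        )
        assert global_importance(attr).ranked_features == \
            global_importance(shuffled).ranked_features


class TestClusterExplanations:
    def _attr(self, phi: np.ndarray) -> AttributionMatrix:
        return AttributionMatrix(
            pd.DataFrame(phi), 0.0, np.zeros(len(phi)), "tree", 1e-6, ""
        )

    def test_planted_blobs_recovered(self):
        rng = np.random.default_rng(0)
        blob1 = rng.normal(0, 0.1, size=(20, 3))
        blob2 = rng.normal(8, 0.1, size=(15, 3))
        clusters = cluster_explanations(self._attr(np.vstack([blob1, blob2])), 2)
        labels = clusters.labels
        assert len(set(labels[:20])) == 1
        assert len(set(labels[20:])) == 1
        assert labels[0] != labels[-1]

    def test_k_equals_n_gives_singletons(self):
        phi = np.arange(12.0).reshape(4, 3)
        clusters = cluster_explanations(self._attr(phi), 4)
        assert sorted(clusters.labels.tolist()) == [1, 2, 3, 4]
        for i, lab in enumerate(clusters.labels):
            assert clusters.cluster_mean_sum[int(lab)] == \
                pytest.approx(phi[i].sum())

    def test_cluster_sizes_sum_to_n(self):
        rng = np.random.default_rng(1)
        attr = self._attr(rng.normal(size=(30, 4)))
        clusters = cluster_explanations(attr, 5)
        assert len(clusters.labels) == 30
        assert set(clusters.labels) == {1, 2, 3, 4, 5}

    def test_deterministic_and_k_bounds(self):
        rng = np.random.default_rng(2)
        attr = self._attr(rng.normal(size=(10, 3)))
        a = cluster_explanations(attr, 3)
        b = cluster_explanations(attr, 3)
        assert np.array_equal(a.labels, b.labels)
        with pytest.raises(ValueError):
            cluster_explanations(attr, 11)


class TestDependenceProfile:
    def test_length_and_constant_model(self, fitted_gbt):
        model, X, y = fitted_gbt
        attr = compute_attributions(model, X)
        feat = attr.phi.columns[0]
        prof = dependence_profile(attr, X, feat)
        assert len(prof) == len(X)

    def test_monotone_model_gives_nondecreasing_trend(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame({"f": rng.uniform(0, 10, 300),
                          "g": rng.normal(size=300)})
        y = (X.f + rng.normal(0, 1.0, 300) > 5).astype(int)
        model = LogisticRegression(max_iter=1000).fit(X, y)
        attr = compute_attributions(model, X)
        prof = dependence_profile(attr, X, "f")
        order = np.argsort(prof["value"].to_numpy())
        trend = prof["trend"].to_numpy()[order]
        assert np.all(np.diff(trend) >= -1e-6)

    def test_flat_profile_for_ignored_feature(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame({"used": rng.normal(size=100),
                          "dummy": rng.normal(size=100)})
        y = (X.used > 0).astype(int)
        model = XGBClassifier(n_estimators=5, max_depth=1, tree_method="hist",
                              eval_metric="logloss", random_state=0).fit(X, y)
        attr = compute_attributions(model, X)
        prof = dependence_profile(attr, X, "dummy")
        assert np.all(prof["phi"] == 0.0)
        assert np.allclose(prof["trend"], 0.0)


class TestMarginalCurve:
    def test_prefix_consistency_and_duplicate_feature(self, xy_small):
        X, y = xy_small
        Xd = X.iloc[:, :3].copy()
        Xd["dup"] = Xd.iloc[:, 0]
        spec = ClassifierSpec("gbt", {"n_estimators": [30]})
        ranked = [Xd.columns[0], "dup", Xd.columns[1]]
        curve = marginal_importance_curve(Xd, y, ranked, spec, k=4, seed=0)
        assert len(curve) == 3
        single = tune_and_evaluate(Xd[[ranked[0]]], y, spec, k=4, seed=0)
        assert curve.loc[0, "mean_auc"] == pytest.approx(single.mean_auc)
        gain = curve.loc[1, "mean_auc"] - curve.loc[0, "mean_auc"]
        assert abs(gain) <= 0.01

    def test_unknown_feature_rejected(self, xy_small):
        X, y = xy_small
        with pytest.raises(KeyError):
            marginal_importance_curve(
                X, y, ["nope"], ClassifierSpec("gbt"), k=3, seed=0
            )


class TestCorrelationNetwork:
    def test_moderate_pair_connected_at_default_threshold(self):
        rho = pd.DataFrame(
            [[1.0, 0.69, 0.1], [0.69, 1.0, 0.2], [0.1, 0.2, 1.0]],
            columns=list("abc"), index=list("abc"),
        )
        edges, components = correlation_network(rho, 0.5)
        assert ("a", "b", 0.69) in edges
        assert ["a", "b"] in components
        assert all("c" not in comp for comp in components)

    def test_identity_matrix_drops_everything(self):
        rho = pd.DataFrame(np.eye(4), columns=list("abcd"), index=list("abcd"))
        edges, components = correlation_network(rho, 0.5)
        assert edges == [] and components == []

    def test_threshold_boundary_inclusive_and_sign_blind(self):
        rho = pd.DataFrame(
            [[1.0, -0.5], [-0.5, 1.0]], columns=["a", "b"], index=["a", "b"]
        )
        edges, _ = correlation_network(rho, 0.5)
        assert len(edges) == 1

    def test_asymmetric_input_rejected(self):
        bad = pd.DataFrame([[1.0, 0.3], [0.6, 1.0]])
        with pytest.raises(ValueError, match="symmetric"):
            correlation_network(bad, 0.5)
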