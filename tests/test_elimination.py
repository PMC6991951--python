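"""Model reliance and the incremental feature-elimination wrapper."""

import numpy as np
import pandas as pd
import pytest
from sklearn.tree import DecisionTreeClassifier

from relifex import ClassifierSpec, model_reliance, run_ife, select_best
from relifex.classification import CVResult
from relifex.elimination import EliminationTrace, IterationRecord
from oracles import expected_permuted_error


@pytest.fixture()
def stump_on_first_feature():
    """Depth-1 tree that splits on feature 'a' and provably ignores 'b'."""
    rng = np.random.default_rng(0)
    X = pd.DataFrame({"a": np.repeat([0.0, 1.0], 20),
                      "b": rng.normal(size=40)})
    y = np.repeat([0, 1], 20)
    model = DecisionTreeClassifier(max_depth=1, random_state=0).fit(X, y)
    assert model.tree_.feature[0] == 0  # split is on 'a'
    return model, X, y


class TestModelReliance:
    def test_ignored_feature_has_reliance_exactly_one(self, stump_on_first_feature):
        model, X, y = stump_on_first_feature
        score = model_reliance(model, X, y, "b", n_perm=10, seed=0)
        assert score.e_perm_mean == score.e_orig
        assert score.mr == 1.0
        assert score.mr_raw == 1.0 or np.isnan(score.mr_raw)

    def test_used_feature_has_reliance_above_one(self, stump_on_first_feature):
        model, X, y = stump_on_first_feature
        score = model_reliance(model, X, y, "a", n_perm=10, seed=0)
        assert score.mr > 1.0
        assert score.e_perm_mean > score.e_orig

    def test_sampled_estimate_tracks_exhaustive_enumeration(self):
        # 5 rows: all 120 permutations enumerable in closed form
        X = pd.DataFrame({"f": [0.0, 1.0, 2.0, 3.0, 4.0]})
        y = np.array([0, 0, 0, 1, 1])
        model = DecisionTreeClassifier(max_depth=1, random_state=0).fit(X, y)
        exact = expected_permuted_error(model, X, y, "f")
        estimates = [
            model_reliance(model, X, y, "f", n_perm=10, seed=s).e_perm_mean
            for s in range(60)
        ]
        grand = np.mean(estimates)
        mc_sd = np.std(estimates, ddof=1) / np.sqrt(len(estimates))
        assert abs(grand - exact) <= 3 * mc_sd + 1e-12

    def test_more_permutations_reduce_estimator_spread(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame({"f": rng.normal(size=60),
                          "g": rng.normal(size=60)})
        y = (X["f"] + rng.normal(0, 0.3, 60) > 0).astype(int)
        model = DecisionTreeClassifier(max_depth=3, random_state=0).fit(X, y)
        small = [model_reliance(model, X, y, "f", n_perm=5, seed=s).mr
                 for s in range(25)]
        large = [model_reliance(model, X, y, "f", n_perm=100, seed=s).mr
                 for s in range(25)]
        assert np.std(large) < np.std(small)

    def test_errors(self, stump_on_first_feature):
        model, X, y = stump_on_first_feature
        with pytest.raises(KeyError):
            model_reliance(model, X, y, "missing", n_perm=10, seed=0)
        with pytest.raises(ValueError):
            model_reliance(model, X, y, "a", n_perm=0, seed=0)

    def test_permutations_seeded_reproducibly(self, stump_on_first_feature):
        model, X, y = stump_on_first_feature
        a = model_reliance(model, X, y, "a", n_perm=10, seed=5)
        b = model_reliance(model, X, y, "a", n_perm=10, seed=5)
        assert a.e_perm_mean == b.e_perm_mean


class TestRunIFE:
    def test_trace_shrinks_and_terminates(self, xy_small):
        X, y = xy_small
        spec = ClassifierSpec("gbt", {"max_depth": [3], "n_estimators": [40]})
        trace = run_ife(X, y, spec, k=4, n_perm=5, master_seed=0, max_iter=25)
        sizes = [rec.n_features for rec in trace.iterations]
        assert all(a > b for a, b in zip(sizes, sizes[1:]))
        assert len(trace.iterations) <= min(X.shape[1], 25)
        assert trace.termination_reason in (
            "all_mr_le_1", "feature_set_unchanged", "max_iter"
        )
        for earlier, later in zip(trace.iterations, trace.iterations[1:]):
            assert set(later.features) <= set(earlier.features)

    def test_unchanged_feature_set_stops_wrapper(self, xy_small):
        X, y = xy_small
        spec = ClassifierSpec("gbt", {"max_depth": [3], "n_estimators": [40]})
        trace = run_ife(X, y, spec, k=4, n_perm=5, master_seed=0, max_iter=25)
        if trace.termination_reason == "feature_set_unchanged":
            last = trace.iterations[-1]
            retained = [f for f in last.features if last.reliance[f].mr > 1.0]
            assert retained == last.features

    def test_reproducible_trace(self, xy_small):
        X, y = xy_small
        spec = ClassifierSpec("gbt", {"max_depth": [2]})
        t1 = run_ife(X, y, spec, k=3, n_perm=3, master_seed=4, max_iter=4)
        t2 = run_ife(X, y, spec, k=3, n_perm=3, master_seed=4, max_iter=4)
        assert [r.features for r in t1.iterations] == \
            [r.features for r in t2.iterations]
        assert [r.cv.fold_aucs for r in t1.iterations] == \
            [r.cv.fold_aucs for r in t2.iterations]

    def test_empty_feature_set_rejected(self):
        with pytest.raises(ValueError):
            run_ife(pd.DataFrame(index=range(10)), np.zeros(10),
                    ClassifierSpec("gbt"))

    def test_trace_serializes(self, xy_small):
        import json

        X, y = xy_small
        trace = run_ife(X, y, ClassifierSpec("cart", {"max_depth": [2]}),
                        k=3, n_perm=2, master_seed=0, max_iter=2)
        blob = json.dumps(trace.to_records())
        assert json.loads(blob)[0]["iteration"] == 1


def _fake_trace(classifier: str, aucs_and_p: list[tuple[float, int]]):
    records = []
    for i, (mean_auc, p) in enumerate(aucs_and_p, start=1):
        cv = CVResult(
            classifier=classifier,
            fold_aucs=[mean_auc] * 10,
            mean_auc=mean_auc,
            sd_auc=0.0,
            ci95=(mean_auc, mean_auc),
            params={},
            n_features=p,
        )
        records.append(IterationRecord(i, [f"f{j}" for j in range(p)], cv, {}))
    return EliminationTrace(classifier, records, "all_mr_le_1")


class TestSelectBest:
    def test_highest_auc_wins(self):
        gbt = _fake_trace("gbt", [(0.880, 205), (0.890, 26)])
        ridge = _fake_trace("ridge", [(0.873, 205), (0.876, 127)])
        clf, iteration, cv, feats = select_best([gbt, ridge])
        assert clf == "gbt"
        assert iteration == 2
        assert cv.mean_auc == 0.890
        assert len(feats) == 26

    def test_tie_broken_by_fewer_features(self):
        a = _fake_trace("rf", [(0.85, 31)])
        b = _fake_trace("nb", [(0.85, 26)])
        clf, _, cv, feats = select_best([a, b])
        assert clf == "nb"
        assert len(feats) == 26

    def test_tie_on_features_broken_by_roster_order(self):
        a = _fake_trace("ridge", [(0.85, 26)])
        b = _fake_trace("rf", [(0.85, 26)])
        clf, *_ = select_best([a, b])
        assert clf == "rf"  # rf precedes ridge in the roster

    def test_single_trace(self):
        t = _fake_trace("gbt", [(0.7, 10), (0.8, 5), (0.75, 3)])
        clf, iteration, *_ = select_best([t])
        assert (clf, iteration) == ("gbt", 2)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            select_best([])
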