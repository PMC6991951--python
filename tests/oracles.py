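"""Independent brute-force oracles used by the test suite.

These deliberately re-derive quantities from first principles (pair
counting, permutation enumeration, coalition enumeration, tree walking)
and never call the implementation paths they check.
"""

from __future__ import annotations

import itertools
import json
import math

import numpy as np


def auc_pair_counting(scores, labels) -> float:
    """AUC as the tie-corrected fraction of concordant (+,-) pairs."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    pos = scores[labels == classes[-1]]
    neg = scores[labels == classes[0]]
    total = concordant = 0.0
    for sp in pos:
        for sn in neg:
            total += 1
            if sp > sn:
                concordant += 1
            elif sp == sn:
                concordant += 0.5
    return concordant / total


def expected_permuted_error(model, X, y, feature: str) -> float:
    """Mean 0/1 error over ALL permutations of one feature column."""
    n = len(X)
    errors = []
    col = X[feature].to_numpy()
    Xp = X.copy()
    for perm in itertools.permutations(range(n)):
        Xp[feature] = col[list(perm)]
        pred = model.predict_proba(Xp)[:, -1] > 0.5
        errors.append(np.mean(pred != y.astype(bool)))
    return float(np.mean(errors))


def shapley_brute_force(value_fn, n_features: int) -> np.ndarray:
    """Exact Shapley values by enumerating all 2^M coalitions.

    ``value_fn(frozenset)`` returns the (vector) value of a coalition.
    """
    M = n_features
    fact = [math.factorial(i) for i in range(M + 1)]
    values = {
        frozenset(S): np.asarray(value_fn(frozenset(S)), dtype=float)
        for r in range(M + 1)
        for S in itertools.combinations(range(M), r)
    }
    phi = [np.zeros_like(values[frozenset()]) for _ in range(M)]
    for j in range(M):
        for r in range(M):
            for S in itertools.combinations([i for i in range(M) if i != j], r):
                S = frozenset(S)
                w = fact[len(S)] * fact[M - len(S) - 1] / fact[M]
                phi[j] = phi[j] + w * (values[S | {j}] - values[S])
    return np.stack(phi, axis=-1)


def tree_value_function(booster, x: np.ndarray, coalition: frozenset,
                        base_offset: float) -> float:
    """Cover-weighted tree-ensemble expectation given a feature coalition.

    Splits on coalition features follow the instance; all other splits
    average both children weighted by training cover.
    """
    total = base_offset
    for dump in booster.get_dump(dump_format="json", with_stats=True):
        def walk(node) -> float:
            if "leaf" in node:
                return float(node["leaf"])
            name = node["split"]
            col = int(name[1:]) if name.startswith("f") and name[1:].isdigit() \
                else name
            children = {c["nodeid"]: c for c in node["children"]}
            low, high = children[node["yes"]], children[node["no"]]
            if col in coalition:
                xv = np.float32(x[col])
                return walk(low) if xv < np.float32(node["split_condition"]) \
                    else walk(high)
            cover = float(node["cover"])
            return (
                float(low["cover"]) / cover * walk(low)
                + float(high["cover"]) / cover * walk(high)
            )

        total += walk(json.loads(dump))
    return total


def interventional_value_function(margin_fn, x: np.ndarray,
                                  background: np.ndarray,
                                  coalition: frozenset) -> float:
    """E_z[f(x_S, z_{-S})] over an explicit background sample."""
    hybrid = background.copy()
    for j in coalition:
        hybrid[:, j] = x[j]
    return float(np.mean(margin_fn(hybrid)))
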