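"""Pluggable binary classifiers under stratified k-fold CV with grid search.

The roster mirrors the common algorithm families for tabular questionnaire
data: gradient boosted trees, random forest, L1/L2-penalized logistic
regression, distance-weighted k-NN, Gaussian naive Bayes, CART decision
tree, SVM and a single-hidden-layer neural net.  Every roster member
exposes predicted probabilities (margin-based learners through their
standard probability mapping) so that reliance scores and threshold
metrics share one score contract.  Model selection maximizes mean
out-of-fold AUC over a finite hyperparameter grid; the winning
configuration is refit on all rows.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.linear_model import LogisticRegression
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from xgboost import XGBClassifier

__all__ = [
    "ROSTER",
    "ClassifierSpec",
    "CVResult",
    "ThresholdMetrics",
    "make_estimator",
    "stratified_kfold",
    "auc",
    "tune_and_evaluate",
    "threshold_metrics",
    "default_roster_specs",
]

# Roster order doubles as the documented tie-break order in model selection.
ROSTER = ("gbt", "rf", "lasso", "ridge", "wknn", "nb", "cart", "svm", "nnet")

_SCALED = {"lasso", "ridge", "wknn", "svm", "nnet"}


@dataclass(frozen=True)
class ClassifierSpec:
    """Algorithm id plus a finite hyperparameter grid (name -> value list)."""

    algorithm: str
    grid: Mapping[str, Sequence] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.algorithm not in ROSTER:
            raise ValueError(
                f"unknown algorithm {self.algorithm!r}; roster: {ROSTER}"
            )
        for name, values in self.grid.items():
            if len(list(values)) == 0:
                raise ValueError(f"grid entry {name!r} has no values")


@dataclass
class CVResult:
    classifier: str
    fold_aucs: list[float]
    mean_auc: float
    sd_auc: float
    ci95: tuple[float, float]
    params: dict
    n_features: int
    model: object | None = None

    def __post_init__(self) -> None:
        for a in self.fold_aucs:
            if not (0.0 <= a <= 1.0):
                raise ValueError(f"fold AUC {a} outside [0, 1]")


@dataclass
class ThresholdMetrics:
    threshold: float
    accuracy: float
    sensitivity: float
    specificity: float
    precision: float          # NaN when no instance is predicted positive
    npv: float                # NaN when no instance is predicted negative
    precision_defined: bool = True
    npv_defined: bool = True


def make_estimator(algorithm: str, seed: int = 0):
    """Fresh estimator for a roster id; scaling-sensitive learners come
    wrapped in a StandardScaler pipeline (step name ``clf``)."""
    if algorithm == "gbt":
        est = XGBClassifier(
            n_estimators=100,
            max_depth=3,
            learning_rate=0.1,
            tree_method="hist",
            eval_metric="logloss",
            n_jobs=1,
            random_state=seed,
        )
    elif algorithm == "rf":
        est = RandomForestClassifier(
            n_estimators=200, max_features="sqrt", n_jobs=1, random_state=seed
        )
    elif algorithm == "lasso":
        est = LogisticRegression(
            l1_ratio=1, solver="liblinear", max_iter=5000, random_state=seed
        )
    elif algorithm == "ridge":
        est = LogisticRegression(solver="lbfgs", max_iter=5000, random_state=seed)
    elif algorithm == "wknn":
        est = KNeighborsClassifier(weights="distance", n_neighbors=15)
    elif algorithm == "nb":
        est = GaussianNB()
    elif algorithm == "cart":
        est = DecisionTreeClassifier(max_depth=4, random_state=seed)
    elif algorithm == "svm":
        est = SVC(probability=True, random_state=seed)
    elif algorithm == "nnet":
        est = MLPClassifier(
            hidden_layer_sizes=(16,), max_iter=800, random_state=seed
        )
    else:
        raise ValueError(f"unknown algorithm {algorithm!r}; roster: {ROSTER}")
    if algorithm in _SCALED:
        return Pipeline([("scale", StandardScaler()), ("clf", est)])
    return est


def _set_params(est, algorithm: str, params: Mapping) -> None:
    if algorithm in _SCALED:
        est.set_params(**{f"clf__{k}": v for k, v in params.items()})
    else:
        est.set_params(**params)


def default_roster_specs(reduced: bool = False) -> list[ClassifierSpec]:
    """Representative grids for the full roster (smaller if ``reduced``)."""
    if reduced:
        grids = {
            "gbt": {"max_depth": [3], "n_estimators": [100]},
            "rf": {"n_estimators": [200]},
            "lasso": {"C": [0.1, 1.0]},
            "ridge": {"C": [0.1, 1.0]},
            "wknn": {"n_neighbors": [15]},
            "nb": {},
            "cart": {"max_depth": [4]},
            "svm": {"C": [1.0]},
            "nnet": {"hidden_layer_sizes": [(16,)]},
        }
    else:
        grids = {
            "gbt": {"max_depth": [2, 3, 4], "n_estimators": [100, 200]},
            "rf": {"n_estimators": [200, 400], "max_features": ["sqrt", 0.33]},
            "lasso": {"C": [0.01, 0.1, 1.0, 10.0]},
            "ridge": {"C": [0.01, 0.1, 1.0, 10.0]},
            "wknn": {"n_neighbors": [5, 15, 31]},
            "nb": {"var_smoothing": [1e-9, 1e-7]},
            "cart": {"max_depth": [2, 4, 8]},
            "svm": {"C": [0.1, 1.0, 10.0]},
            "nnet": {"hidden_layer_sizes": [(8,), (16,), (32,)]},
        }
    return [ClassifierSpec(a, grids[a]) for a in ROSTER]


def stratified_kfold(labels, k: int, seed: int) -> np.ndarray:
    """Stratified fold assignment (array of fold ids in 0..k-1).

    Per-fold class counts differ from exact proportionality by at most 1.
    Raises if any class has fewer than k members.
    """
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < k:
        small = classes[counts.argmin()]
        raise ValueError(
            f"class {small!r} has {counts.min()} members, fewer than k={k}"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignment = np.empty(len(y), dtype=int)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(len(y)), y)):
        assignment[test_idx] = fold
    return assignment


def auc(scores, labels) -> float:
    """Area under the ROC curve: the tie-corrected probability that a
    random positive outranks a random negative."""
    y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("AUC requires both classes present")
    # the larger label (sorted order) is the positive class, matching
    # sklearn's classes_ convention used for probability columns
    return float(roc_auc_score(y == classes[-1], np.asarray(scores, dtype=float)))


def _positive_proba(model, X) -> np.ndarray:
    proba = model.predict_proba(X)
    classes = model.classes_ if hasattr(model, "classes_") else model[-1].classes_
    pos_col = int(np.argmax(classes))  # classes_ is sorted; last is positive
    return proba[:, pos_col]


def tune_and_evaluate(
    X: pd.DataFrame,
    y,
    spec: ClassifierSpec,
    k: int = 10,
    seed: int = 0,
) -> CVResult:
    """Grid search scored by mean out-of-fold AUC over stratified k folds.

    The same fold assignment is reused for every grid point.  The winning
    configuration's per-fold AUCs, mean, SD (ddof=1) and normal 95% CI
    (mean +/- 1.96 SD / sqrt(k)) are returned, together with a final model
    refit on all rows with the selected hyperparameters.
    """
    X = pd.DataFrame(X)
    y = np.asarray(y)
    assignment = stratified_kfold(y, k, seed)
    names = list(spec.grid.keys())
    points = list(itertools.product(*(list(spec.grid[n]) for n in names))) or [()]

    best: tuple[float, list[float], dict] | None = None
    for point in points:
        params = dict(zip(names, point))
        fold_aucs = []
        for fold in range(k):
            test = assignment == fold
            est = make_estimator(spec.algorithm, seed=seed)
            _set_params(est, spec.algorithm, params)
            ytr = y[~test]
            if len(np.unique(ytr)) < 2:
                raise ValueError(f"training fold {fold} is single-class")
            est.fit(X.loc[~test], ytr)
            fold_aucs.append(auc(_positive_proba(est, X.loc[test]), y[test]))
        mean = float(np.mean(fold_aucs))
        if best is None or mean > best[0]:
            best = (mean, fold_aucs, params)

    mean, fold_aucs, params = best
    sd = float(np.std(fold_aucs, ddof=1)) if k > 1 else 0.0
    half = 1.96 * sd / np.sqrt(k)
    final = make_estimator(spec.algorithm, seed=seed)
    _set_params(final, spec.algorithm, params)
    final.fit(X, y)
    return CVResult(
        classifier=spec.algorithm,
        fold_aucs=[float(a) for a in fold_aucs],
        mean_auc=mean,
        sd_auc=sd,
        ci95=(mean - half, mean + half),
        params=params,
        n_features=X.shape[1],
        model=final,
    )


def threshold_metrics(scores, labels, threshold: float = 0.5) -> ThresholdMetrics:
    """Confusion-matrix metrics with the positive class predicted at
    score > threshold."""
    if not (0.0 <= threshold <= 1.0):
        raise ValueError(f"threshold {threshold} outside [0, 1]")
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    pred = s > threshold
    tp = int(np.sum(pred & y))
    fp = int(np.sum(pred & ~y))
    fn = int(np.sum(~pred & y))
    tn = int(np.sum(~pred & ~y))
    n = tp + fp + fn + tn
    precision_defined = (tp + fp) > 0
    npv_defined = (tn + fn) > 0
    return ThresholdMetrics(
        threshold=threshold,
        accuracy=(tp + tn) / n,
        sensitivity=tp / (tp + fn) if (tp + fn) else float("nan"),
        specificity=tn / (tn + fp) if (tn + fp) else float("nan"),
        precision=tp / (tp + fp) if precision_defined else float("nan"),
        npv=tn / (tn + fn) if npv_defined else float("nan"),
        precision_defined=precision_defined,
        npv_defined=npv_defined,
    )
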