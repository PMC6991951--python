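"""Model reliance and the incremental feature-elimination (IFE) wrapper.

Model reliance (MR) scores a fitted model's dependence on one feature by
the ratio of the classification error after randomly permuting that
feature's column to the error on the unpermuted training data:

    MR(f, zeta) = e_perm / e_orig,
    e_orig = CE(y, zeta(X_orig)),  e_perm = CE(y, zeta(X_perm)),

averaged over ``n_perm`` independent permutations (default 10) for a more
stable estimate.  CE is 0/1 misclassification at probability 0.5 by
default; 1 - AUC can be chosen instead.  MR > 1 means permutation hurt the
model, i.e. the model relies on the feature.

The IFE wrapper starts from the full feature set, tunes and fits a
classifier, computes MR for every current feature, keeps exactly the
features with MR > 1, and iterates.  It stops when no MR exceeds 1, when
the feature set stops changing, or at ``max_iter``.  Because the retained
set is a subset of the current one, the feature count is non-increasing
and the wrapper terminates within min(p, max_iter) iterations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .classification import (
    ClassifierSpec,
    CVResult,
    ROSTER,
    _positive_proba,
    auc,
    tune_and_evaluate,
)

__all__ = [
    "RelianceScore",
    "IterationRecord",
    "EliminationTrace",
    "classification_error",
    "model_reliance",
    "run_ife",
    "select_best",
]

# Child-seed offsets inside one IFE run.
_SEED_CV = 101
_SEED_PERM_STRIDE = 7919  # per-iteration stride for permutation streams


@dataclass
class RelianceScore:
    feature: str
    e_orig: float
    e_perm_mean: float
    mr: float                 # smoothed ratio, finite by construction
    mr_raw: float             # unsmoothed e_perm_mean / e_orig (inf/nan possible)
    n_perm: int
    seed: int


@dataclass
class IterationRecord:
    iteration: int
    features: list[str]
    cv: CVResult
    reliance: dict[str, RelianceScore]

    @property
    def n_features(self) -> int:
        return len(self.features)


TerminationReason = Literal["all_mr_le_1", "feature_set_unchanged", "max_iter"]


@dataclass
class EliminationTrace:
    classifier: str
    iterations: list[IterationRecord]
    termination_reason: TerminationReason

    @property
    def best_iteration(self) -> IterationRecord:
        return max(self.iterations, key=lambda r: (r.cv.mean_auc, -r.n_features))

    def to_records(self) -> list[dict]:
        """JSON-serializable trace (one object per iteration)."""
        out = []
        for rec in self.iterations:
            out.append(
                {
                    "iteration": rec.iteration,
                    "features": rec.features,
                    "n_features": rec.n_features,
                    "params": rec.cv.params,
                    "fold_aucs": rec.cv.fold_aucs,
                    "mean_auc": rec.cv.mean_auc,
                    "sd_auc": rec.cv.sd_auc,
                    "ci95": list(rec.cv.ci95),
                    "reliance": {
                        f: {
                            "e_orig": s.e_orig,
                            "e_perm_mean": s.e_perm_mean,
                            "mr": s.mr,
                        }
                        for f, s in rec.reliance.items()
                    },
                }
            )
        return out


def classification_error(model, X: pd.DataFrame, y: np.ndarray,
                         loss: str = "zero_one") -> float:
    """CE used by model reliance: 0/1 misclassification at probability 0.5
    (default), or 1 - AUC behind the ``auc`` flag."""
    scores = _positive_proba(model, X)
    y = np.asarray(y)
    classes = np.unique(y)
    if loss == "zero_one":
        pred_pos = scores > 0.5
        actual_pos = y == classes[-1] if len(classes) == 2 else y.astype(bool)
        return float(np.mean(pred_pos != actual_pos))
    if loss == "auc":
        return 1.0 - auc(scores, y)
    raise ValueError(f"unknown loss {loss!r}")


def model_reliance(
    model,
    X: pd.DataFrame,
    y,
    feature: str,
    n_perm: int = 10,
    seed: int = 0,
    loss: str = "zero_one",
) -> RelianceScore:
    """Permutation-based reliance of ``model`` on one feature column.

    ``e_orig`` is computed once on the unpermuted data; each of ``n_perm``
    seeded permutations of the feature's column yields one permuted error,
    and their mean enters the smoothed ratio

        mr = (e_perm_mean + eps) / (e_orig + eps),  eps = 0.5 / n,

    which stays finite on perfect fits and equals 1 whenever the two errors
    are equal (in particular, exactly 1 for a feature the model ignores).
    """
    if feature not in X.columns:
        raise KeyError(f"feature {feature!r} not in X")
    if n_perm < 1:
        raise ValueError(f"n_perm must be >= 1, got {n_perm}")
    y = np.asarray(y)
    n = len(X)
    e_orig = classification_error(model, X, y, loss=loss)
    rng = np.random.default_rng(seed)
    X_perm = X.copy()
    col = X[feature].to_numpy()
    errors = np.empty(n_perm)
    for i in range(n_perm):
        X_perm[feature] = col[rng.permutation(n)]
        errors[i] = classification_error(model, X_perm, y, loss=loss)
    e_perm_mean = float(errors.mean())
    eps = 0.5 / n
    with np.errstate(divide="ignore", invalid="ignore"):
        mr_raw = e_perm_mean / e_orig if e_orig > 0 else float("inf") \
            if e_perm_mean > 0 else float("nan")
    return RelianceScore(
        feature=feature,
        e_orig=e_orig,
        e_perm_mean=e_perm_mean,
        mr=(e_perm_mean + eps) / (e_orig + eps),
        mr_raw=mr_raw,
        n_perm=n_perm,
        seed=seed,
    )


def run_ife(
    X: pd.DataFrame,
    y,
    spec: ClassifierSpec,
    k: int = 10,
    n_perm: int = 10,
    master_seed: int = 0,
    max_iter: int = 25,
    loss: str = "zero_one",
) -> EliminationTrace:
    """Incremental feature elimination for one classifier.

    Each iteration i tunes the classifier on the current feature set F_i by
    stratified k-fold grid search (hyperparameters are re-tuned every
    iteration), refits on all rows, computes MR for every f in F_i on the
    training data, and retains F_{i+1} = {f : MR(f) > 1}.  Stops when all
    MR <= 1, when F_{i+1} = F_i, or after ``max_iter`` iterations; the full
    per-iteration trace is returned.
    """
    X = pd.DataFrame(X)
    if X.shape[1] == 0:
        raise ValueError("empty initial feature set")
    y = np.asarray(y)
    features = list(X.columns)
    records: list[IterationRecord] = []
    reason: TerminationReason = "max_iter"
    for it in range(1, max_iter + 1):
        Xi = X[features]
        cv = tune_and_evaluate(Xi, y, spec, k=k, seed=master_seed + _SEED_CV)
        perm_base = master_seed + _SEED_PERM_STRIDE * it
        reliance = {
            f: model_reliance(
                cv.model, Xi, y, f, n_perm=n_perm, seed=perm_base + j, loss=loss
            )
            for j, f in enumerate(features)
        }
        records.append(IterationRecord(it, list(features), cv, reliance))
        retained = [f for f in features if reliance[f].mr > 1.0]
        if not retained:
            reason = "all_mr_le_1"
            break
        if retained == features:
            reason = "feature_set_unchanged"
            break
        features = retained
    return EliminationTrace(
        classifier=spec.algorithm, iterations=records, termination_reason=reason
    )


def select_best(
    traces: Sequence[EliminationTrace],
) -> tuple[str, int, CVResult, list[str]]:
    """Best (classifier, iteration) over all traces by mean CV AUC.

    Ties break toward fewer features, then by roster order of the
    classifier.  Returns (classifier id, iteration number, CVResult,
    feature set).
    """
    if not traces:
        raise ValueError("select_best needs at least one trace")
    candidates = []
    for trace in traces:
        roster_pos = ROSTER.index(trace.classifier) if trace.classifier in ROSTER \
            else len(ROSTER)
        for rec in trace.iterations:
            candidates.append(
                (
                    -rec.cv.mean_auc,
                    rec.n_features,
                    roster_pos,
                    trace.classifier,
                    rec,
                )
            )
    candidates.sort(key=lambda c: c[:3])
    _, _, _, classifier, rec = candidates[0]
    return classifier, rec.iteration, rec.cv, list(rec.features)
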