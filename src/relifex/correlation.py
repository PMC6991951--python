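"""Spearman correlation analytics: feature-feature structure and
feature-distress correlations at both time points.

Rank correlations use average ranks for ties.  Constant columns get an
explicitly undefined (NaN) correlation rather than a silent zero and are
excluded from questionnaire medians.  Feature ordering for heatmap-style
output comes from agglomerative hierarchical clustering with complete
linkage on the signed distance 1 - rho, which keeps positively and
negatively polarized feature groups apart.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform

__all__ = [
    "spearman_matrix",
    "order_by_clustering",
    "target_correlations",
    "TargetCorrelations",
]


def _rank_transform(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column-wise average ranks; returns (ranks, constant-column mask)."""
    ranks = np.apply_along_axis(stats.rankdata, 0, X)
    constant = ranks.std(axis=0) == 0
    return ranks, constant


def spearman_matrix(X: pd.DataFrame | np.ndarray) -> pd.DataFrame:
    """Full p x p Spearman matrix with average ranks for ties.

    Entries involving a constant column are NaN (flagged undefined); the
    diagonal is 1 everywhere, including for constant columns.
    """
    df = pd.DataFrame(X)
    arr = df.to_numpy(dtype=float)
    n, p = arr.shape
    if n < 3:
        raise ValueError(f"need at least 3 observations, got {n}")
    ranks, constant = _rank_transform(arr)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.corrcoef(ranks, rowvar=False)
    rho = np.atleast_2d(rho)
    rho[constant, :] = np.nan
    rho[:, constant] = np.nan
    np.fill_diagonal(rho, 1.0)
    rho = np.clip(rho, -1.0, 1.0)
    return pd.DataFrame(rho, index=df.columns, columns=df.columns)


def order_by_clustering(
    rho: pd.DataFrame | np.ndarray, fill_value: float | None = None
) -> np.ndarray:
    """Dendrogram leaf order from complete-linkage clustering of 1 - rho.

    Undefined (NaN) entries raise unless ``fill_value`` supplies the
    correlation to use in their place.  The returned permutation indexes
    rows/columns of ``rho``.
    """
    R = pd.DataFrame(rho).to_numpy(dtype=float).copy()
    if R.ndim != 2 or R.shape[0] != R.shape[1]:
        raise ValueError("rho must be square")
    p = R.shape[0]
    if p == 1:
        return np.array([0])
    off_diag = ~np.eye(p, dtype=bool)
    if np.isnan(R[off_diag]).any():
        if fill_value is None:
            raise ValueError(
                "correlation matrix has undefined entries; pass fill_value"
            )
        R[np.isnan(R)] = fill_value
    if not np.allclose(R, R.T, atol=1e-12, equal_nan=True):
        raise ValueError("rho must be symmetric")
    dist = 1.0 - R
    np.fill_diagonal(dist, 0.0)
    # scipy's linkage on a condensed matrix is deterministic: equal-distance
    # merges resolve by the lower pair index.
    Z = linkage(squareform(dist, checks=False), method="complete")
    return np.asarray(leaves_list(Z))


@dataclass
class TargetCorrelations:
    """Per-feature Spearman correlation with the distress score at T0/T1."""

    table: pd.DataFrame            # columns rho_t0, rho_t1, delta_abs
    top_t0: pd.DataFrame           # top-k by |rho_t0|
    top_t1: pd.DataFrame           # top-k by |rho_t1|
    top_delta: pd.DataFrame        # top-k by |rho_t0| - |rho_t1|
    questionnaire_medians: pd.DataFrame  # median rho_t0/rho_t1 per group


def _spearman_vs(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    ranks_y = stats.rankdata(y)
    ranks_X, constant = _rank_transform(X)
    ry = ranks_y - ranks_y.mean()
    rX = ranks_X - ranks_X.mean(axis=0)
    denom = np.sqrt((ry**2).sum()) * np.sqrt((rX**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (rX.T @ ry) / denom
    rho[constant] = np.nan
    return np.clip(rho, -1.0, 1.0)


def target_correlations(
    X: pd.DataFrame,
    tq_t0: np.ndarray,
    tq_t1: np.ndarray,
    questionnaire_of: Mapping[str, str] | None = None,
    k: int = 20,
) -> TargetCorrelations:
    """Feature-distress Spearman correlations before and after treatment.

    Returns per-feature rho at T0 and T1, the top-k features by correlation
    magnitude at each time point, the top-k by shrinkage of magnitude
    |rho_t0| - |rho_t1|, and per-questionnaire medians over the supplied
    membership map (constant features are excluded from medians).
    """
    if not (len(X) == len(tq_t0) == len(tq_t1)):
        raise ValueError("X, tq_t0, tq_t1 must have aligned rows")
    p = X.shape[1]
    if k > p:
        raise ValueError(f"k={k} exceeds feature count {p}")
    arr = X.to_numpy(dtype=float)
    rho_t0 = _spearman_vs(np.asarray(tq_t0, dtype=float), arr)
    rho_t1 = _spearman_vs(np.asarray(tq_t1, dtype=float), arr)
    table = pd.DataFrame(
        {
            "rho_t0": rho_t0,
            "rho_t1": rho_t1,
            "delta_abs": np.abs(rho_t0) - np.abs(rho_t1),
        },
        index=X.columns,
    )
    by_t0 = table.reindex(
        table["rho_t0"].abs().sort_values(ascending=False, kind="stable").index
    )
    by_t1 = table.reindex(
        table["rho_t1"].abs().sort_values(ascending=False, kind="stable").index
    )
    by_delta = table.reindex(
        table["delta_abs"].sort_values(ascending=False, kind="stable").index
    )
    medians = pd.DataFrame(columns=["median_rho_t0", "median_rho_t1"])
    if questionnaire_of:
        groups: dict[str, list[str]] = {}
        for feat, q in questionnaire_of.items():
            groups.setdefault(q, []).append(feat)
        rows = {}
        for q, feats in sorted(groups.items()):
            sub = table.loc[[f for f in feats if f in table.index]]
            sub = sub.dropna(subset=["rho_t0", "rho_t1"])
            rows[q] = (sub["rho_t0"].median(), sub["rho_t1"].median())
        medians = pd.DataFrame(
            rows, index=["median_rho_t0", "median_rho_t1"]
        ).T
    return TargetCorrelations(
        table=table,
        top_t0=by_t0.head(k),
        top_t1=by_t1.head(k),
        top_delta=by_delta.head(k),
        questionnaire_medians=medians,
    )
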