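"""Label discretization, feature encoding and baseline group comparison.

The continuous tinnitus-distress score (0-84) is discretized at a cutoff
(default 46) into "compensated" (score <= cutoff) vs "decompensated"
(score > cutoff).  Ordinal Likert items pass through as numeric columns;
multi-level categoricals expand to exhaustive dichotomous indicators.  The
baseline summary compares the two classes feature by feature with a
caller-chosen test (t-test, Mann-Whitney or chi-squared) under Bonferroni
correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import SCORE_MAX, CohortTable

__all__ = [
    "LabelRule",
    "FeatureMatrix",
    "BaselineRow",
    "BaselineSummary",
    "discretize_distress",
    "encode_features",
    "baseline_table",
]

TestName = Literal["t_test", "mann_whitney", "chi_squared"]


@dataclass(frozen=True)
class LabelRule:
    cutoff: float = 46.0
    class_low: str = "compensated"
    class_high: str = "decompensated"

    def __post_init__(self) -> None:
        if not (0.0 <= self.cutoff <= SCORE_MAX):
            raise ValueError(f"cutoff {self.cutoff} outside [0, {SCORE_MAX}]")


@dataclass
class FeatureMatrix:
    """Numeric modelling matrix plus the categorical -> indicator map."""

    values: pd.DataFrame
    encoding_map: dict[str, list[str]]

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def discretize_distress(score, rule: LabelRule = LabelRule()):
    """Map score(s) to class labels; <= cutoff is the low-distress class."""
    arr = np.asarray(score, dtype=float)
    if np.any(arr < 0) or np.any(arr > SCORE_MAX):
        raise ValueError(f"distress score outside [0, {SCORE_MAX}]")
    labels = np.where(arr > rule.cutoff, rule.class_high, rule.class_low)
    if np.isscalar(score) or arr.ndim == 0:
        return labels.item()
    return labels


def encode_features(
    raw: CohortTable,
    categorical_levels: Mapping[str, Sequence] | None = None,
) -> FeatureMatrix:
    """Build the modelling matrix from a cohort table.

    Likert, dichotomous, timestamp and continuous columns pass through as
    numeric.  Columns listed in ``categorical_levels`` (name -> level list)
    are expanded into one indicator column per level; the expansion is
    exhaustive, so the indicators for one categorical sum to 1 per row.
    """
    if raw.features.isna().any().any():
        bad = raw.features.columns[raw.features.isna().any()].tolist()
        raise ValueError(f"missing values in columns {bad}; no imputation is done")
    categorical_levels = dict(categorical_levels or {})
    known = {"likert", "dichotomous", "continuous", "timestamp"}
    cols: dict[str, np.ndarray] = {}
    encoding_map: dict[str, list[str]] = {}
    for meta in raw.feature_meta:
        if meta.scale not in known:
            raise ValueError(
                f"feature {meta.name!r} has unsupported scale type {meta.scale!r}"
            )
        col = raw.features[meta.name]
        if meta.name in categorical_levels:
            levels = list(categorical_levels[meta.name])
            observed = set(col.unique())
            if not observed.issubset(levels):
                raise ValueError(
                    f"categorical {meta.name!r} has values outside declared "
                    f"levels: {sorted(observed - set(levels))}"
                )
            names = []
            for lev in levels:
                ind_name = f"{meta.name}={lev}"
                cols[ind_name] = (col == lev).astype(float).to_numpy()
                names.append(ind_name)
            encoding_map[meta.name] = names
        else:
            cols[meta.name] = col.to_numpy(dtype=float)
            encoding_map[meta.name] = [meta.name]
    return FeatureMatrix(pd.DataFrame(cols, index=raw.features.index), encoding_map)


@dataclass
class BaselineRow:
    feature: str
    test: TestName
    group_low: str     # "mean +/- sd" or "count (pct)"
    group_high: str
    p_value: float
    significant: bool


@dataclass
class BaselineSummary:
    rows: list[BaselineRow]
    alpha: float
    p_crit: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature": [r.feature for r in self.rows],
                "test": [r.test for r in self.rows],
                "group_low": [r.group_low for r in self.rows],
                "group_high": [r.group_high for r in self.rows],
                "p_value": [r.p_value for r in self.rows],
                "significant": [r.significant for r in self.rows],
            }
        )


def _chi2_stat(table: np.ndarray, continuity: bool) -> tuple[float, float]:
    """Pearson chi-squared on a contingency table, Sum (O-E)^2 / E."""
    chi2, p, _, _ = stats.chi2_contingency(table, correction=continuity)
    return float(chi2), float(p)


def baseline_table(
    X: FeatureMatrix | pd.DataFrame,
    labels: Sequence[str] | np.ndarray,
    test_assignment: Mapping[str, TestName],
    alpha: float = 0.05,
    chi2_continuity: bool = False,
) -> BaselineSummary:
    """Two-group comparison per feature with Bonferroni correction.

    ``test_assignment`` maps each summarized feature to its test; only the
    listed features are compared, and the Bonferroni critical value is
    alpha / number of comparisons.  Continuous tests report mean +/- SD per
    group, chi-squared reports count (percent) of the nonzero level.
    """
    df = X.values if isinstance(X, FeatureMatrix) else X
    labels = np.asarray(labels)
    classes = sorted(pd.unique(labels))
    if len(classes) != 2:
        raise ValueError(f"need exactly two groups, got {classes}")
    lo_mask = labels == classes[0]
    hi_mask = ~lo_mask
    m = len(test_assignment)
    if m == 0:
        raise ValueError("empty test assignment")
    p_crit = alpha / m

    rows: list[BaselineRow] = []
    for feat, test in test_assignment.items():
        if feat not in df.columns:
            raise KeyError(f"feature {feat!r} not in matrix")
        a = df.loc[lo_mask, feat].to_numpy(dtype=float)
        b = df.loc[hi_mask, feat].to_numpy(dtype=float)
        if test == "t_test":
            if min(len(a), len(b)) < 2:
                raise ValueError(f"t-test on {feat!r} needs >= 2 per group")
            _, p = stats.ttest_ind(a, b, equal_var=False)
            fmt = _mean_sd
        elif test == "mann_whitney":
            if min(len(a), len(b)) < 1:
                raise ValueError(f"mann_whitney on {feat!r} needs non-empty groups")
            method = "exact" if max(len(a), len(b)) <= 20 and not _has_ties(a, b) \
                else "asymptotic"
            _, p = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
            fmt = _mean_sd
        elif test == "chi_squared":
            table = np.array(
                [
                    [np.sum(a == 0), np.sum(a != 0)],
                    [np.sum(b == 0), np.sum(b != 0)],
                ]
            )
            if (table.sum(axis=1) == 0).any():
                raise ValueError(f"chi_squared on {feat!r}: empty group")
            _, p = _chi2_stat(table, chi2_continuity)
            fmt = _count_pct
        else:
            raise ValueError(f"unknown test {test!r} for feature {feat!r}")
        rows.append(
            BaselineRow(
                feature=feat,
                test=test,
                group_low=fmt(a),
                group_high=fmt(b),
                p_value=float(p),
                significant=bool(p < p_crit),
            )
        )
    return BaselineSummary(rows=rows, alpha=alpha, p_crit=p_crit)


def _has_ties(a: np.ndarray, b: np.ndarray) -> bool:
    pooled = np.concatenate([a, b])
    return len(np.unique(pooled)) < len(pooled)


def _mean_sd(x: np.ndarray) -> str:
    return f"{x.mean():.1f} ± {x.std(ddof=1):.1f}"


def _count_pct(x: np.ndarray) -> str:
    k = int(np.sum(x != 0))
    return f"{k} ({100.0 * k / len(x):.0f})"
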