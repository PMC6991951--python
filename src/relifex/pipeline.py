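"""Configuration-driven orchestration of the full workflow.

Stages: simulate -> prep -> correlate -> select (IFE for every roster
classifier in the config) -> explain -> report.  Every numeric output is a
deterministic function of the configuration and its master seed; predictors
passed to any classifier are baseline (T0) features only, never the T1
outcome or its discretization.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .attribution import (
    cluster_explanations,
    compute_attributions,
    correlation_network,
    dependence_profile,
    global_importance,
    marginal_importance_curve,
)
from .classification import (
    ClassifierSpec,
    make_estimator,
    _positive_proba,
    _set_params,
    threshold_metrics,
)
from .correlation import order_by_clustering, spearman_matrix, target_correlations
from .elimination import _SEED_CV, EliminationTrace, run_ife, select_best
from .preprocessing import LabelRule, baseline_table, discretize_distress, encode_features
from .synthetic import (
    CohortTable,
    FeatureMeta,
    SyntheticSpec,
    _spec_from_dict,
    generate_cohort,
    read_cohort,
    write_cohort,
)

__all__ = ["RunConfig", "ReportBundle", "load_cohort", "run_pipeline", "STAGES"]

STAGES = ("simulate", "prep", "correlate", "select", "explain", "report")

_KNOWN_KEYS = {
    "synthetic",
    "cohort_csv",
    "cutoff",
    "classifiers",
    "cv_folds",
    "n_perm",
    "seed",
    "max_iter",
    "explain_clusters",
    "network_threshold",
    "top_k",
    "n_dependence_profiles",
    "marginal_curve_max",
    "out_dir",
}


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    out_dir: Path
    synthetic: dict | None = None
    cohort_csv: str | None = None
    cutoff: float = 46.0
    classifiers: list[dict] = field(default_factory=lambda: [{"algorithm": "gbt"}])
    cv_folds: int = 10
    n_perm: int = 10
    seed: int = 0
    max_iter: int = 25
    explain_clusters: int = 5
    network_threshold: float = 0.5
    top_k: int = 20
    n_dependence_profiles: int = 5
    marginal_curve_max: int = 15

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        if (self.synthetic is None) == (self.cohort_csv is None):
            raise ValueError(
                "config must name exactly one input source: "
                "'synthetic' or 'cohort_csv'"
            )
        if self.cohort_csv is not None:
            prefix = Path(self.cohort_csv)
            if not prefix.with_suffix(".csv").exists():
                raise FileNotFoundError(f"cohort file {prefix}.csv does not exist")
        if not self.classifiers:
            raise ValueError("config lists no classifiers")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ValueError("config file must hold a mapping")
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "out_dir" not in raw:
            raise ValueError("config must set out_dir")
        return cls(**raw)

    def classifier_specs(self) -> list[ClassifierSpec]:
        specs = []
        for entry in self.classifiers:
            entry = dict(entry)
            algorithm = entry.pop("algorithm")
            grid = entry.pop("grid", {})
            if entry:
                raise ValueError(
                    f"unknown classifier keys {sorted(entry)} for {algorithm!r}"
                )
            grid = {k: [tuple(v) if isinstance(v, list) else v for v in vals]
                    for k, vals in grid.items()}
            specs.append(ClassifierSpec(algorithm, grid))
        return specs

    def canonical_hash(self) -> str:
        blob = json.dumps(
            {k: (str(v) if isinstance(v, Path) else v)
             for k, v in sorted(self.__dict__.items())},
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class ReportBundle:
    out_dir: Path
    manifest: dict

    @property
    def files(self) -> list[str]:
        return self.manifest["files"]


def load_cohort(path: str | Path) -> CohortTable:
    """Load a cohort CSV (+ optional ``.meta.json`` sidecar).

    Without a sidecar, scale types are inferred from value patterns
    (binary -> dichotomous, small integral -> likert, nonnegative
    ``*_timestamp`` columns -> timestamp, else continuous).
    """
    prefix = Path(path)
    if prefix.suffix == ".csv":
        prefix = prefix.with_suffix("")
    csv_path = prefix.with_suffix(".csv")
    meta_path = prefix.with_suffix(".meta.json")
    if meta_path.exists():
        return read_cohort(prefix)
    df = pd.read_csv(csv_path, float_precision="round_trip")
    for col in ("tq_t0", "tq_t1"):
        if col not in df.columns:
            raise ValueError(f"cohort file {csv_path} lacks required column {col!r}")
    if "patient_id" in df.columns:
        ids = df["patient_id"].astype(str).tolist()
        df = df.drop(columns=["patient_id"])
    else:
        ids = [f"P{i:05d}" for i in range(len(df))]
    if df.isna().any().any():
        rows = df.index[df.isna().any(axis=1)].tolist()[:5]
        cols = df.columns[df.isna().any()].tolist()
        raise ValueError(f"missing values in rows {rows}, columns {cols}")
    non_numeric = [c for c in df.columns
                   if not np.issubdtype(df[c].dtype, np.number)]
    if non_numeric:
        raise ValueError(f"non-numeric cells in columns {non_numeric}")
    tq_t0 = df.pop("tq_t0").to_numpy(dtype=float)
    tq_t1 = df.pop("tq_t1").to_numpy(dtype=float)
    meta = [FeatureMeta(c, c.split("_")[0], _infer_scale(df[c])) for c in df.columns]
    return CohortTable(ids, df, meta, tq_t0, tq_t1)


def _infer_scale(col: pd.Series) -> str:
    vals = col.to_numpy(dtype=float)
    uniq = np.unique(vals)
    if np.isin(uniq, (0.0, 1.0)).all():
        return "dichotomous"
    if np.array_equal(vals, np.round(vals)) and len(uniq) <= 10 and uniq.min() >= 0:
        return "likert"
    if str(col.name).endswith("_timestamp") and vals.min() >= 0:
        return "timestamp"
    return "continuous"


def _elimination_matrix(traces: Sequence[EliminationTrace]) -> pd.DataFrame:
    """Classifier x iteration matrix of 'AUC (p)' cells, '/' once terminated."""
    max_iter = max(len(t.iterations) for t in traces)
    rows = {}
    order = sorted(
        traces, key=lambda t: -max(r.cv.mean_auc for r in t.iterations)
    )
    for trace in order:
        cells = []
        for i in range(max_iter):
            if i < len(trace.iterations):
                rec = trace.iterations[i]
                cells.append(f"{rec.cv.mean_auc:.3f} ({rec.n_features})")
            else:
                cells.append("/")
        rows[trace.classifier] = cells
    return pd.DataFrame(
        rows, index=[f"i={i + 1}" for i in range(max_iter)]
    ).T


def _default_test_assignment(cohort: CohortTable) -> dict[str, str]:
    # dichotomous features get the chi-squared count comparison; ordinal /
    # continuous / timestamp features the rank-based group test
    return {
        m.name: ("chi_squared" if m.scale == "dichotomous" else "mann_whitney")
        for m in cohort.feature_meta
    }


def run_pipeline(
    config: RunConfig, stages: Sequence[str] = STAGES
) -> ReportBundle:
    """Execute the requested stages in order and write all artifacts.

    Stages read their inputs from ``config.out_dir`` when an earlier stage
    already persisted them, so subcommands can be run one at a time.  Any
    stage failure aborts with the stage name after persisting a partial
    manifest.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: list[str] = []
    manifest_path = out / "manifest.json"

    def record(path: Path) -> Path:
        files.append(path.name)
        return path

    cohort: CohortTable | None = None

    def get_cohort() -> CohortTable:
        nonlocal cohort
        if cohort is not None:
            return cohort
        prefix = out / "cohort"
        if prefix.with_suffix(".csv").exists():
            cohort = read_cohort(prefix)
        elif config.cohort_csv is not None:
            cohort = load_cohort(config.cohort_csv)
        else:
            spec = _spec_from_config(config)
            cohort = generate_cohort(spec)
        return cohort

    def get_xy():
        c = get_cohort()
        X = encode_features(c).values
        leak = [f for f in X.columns if "tq_t1" in f.lower() or "tq_t0" in f.lower()]
        if leak:
            raise ValueError(f"T1/T0 outcome columns leaked into predictors: {leak}")
        rule = LabelRule(cutoff=config.cutoff)
        labels = discretize_distress(c.tq_t1, rule)
        y = (np.asarray(labels) == rule.class_high).astype(int)
        return X, y, rule

    try:
        for stage in STAGES:
            if stage not in stages:
                continue
            if stage == "simulate":
                if config.synthetic is None:
                    continue
                c = get_cohort()
                csv_path, meta_path = write_cohort(c, out / "cohort")
                record(csv_path)
                record(meta_path)
            elif stage == "prep":
                c = get_cohort()
                X, y, rule = get_xy()
                summary = baseline_table(
                    X, discretize_distress(c.tq_t1, rule),
                    _default_test_assignment(c),
                )
                df = summary.to_frame()
                df.attrs["p_crit"] = summary.p_crit
                path = record(out / "baseline_summary.tsv")
                with open(path, "w") as fh:
                    fh.write(f"# alpha={summary.alpha} p_crit={summary.p_crit}\n")
                    df.to_csv(fh, sep="\t", index=False)
            elif stage == "correlate":
                c = get_cohort()
                X, _, _ = get_xy()
                rho = spearman_matrix(X)
                rho.to_csv(record(out / "rho_matrix.tsv"), sep="\t")
                order = order_by_clustering(rho, fill_value=0.0)
                pd.Series(rho.columns[order], name="feature").to_csv(
                    record(out / "cluster_order.tsv"), sep="\t", index=False
                )
                qmap = {m.name: m.group for m in c.feature_meta}
                tc = target_correlations(
                    c.features, c.tq_t0, c.tq_t1, qmap,
                    k=min(config.top_k, X.shape[1]),
                )
                tc.table.to_csv(record(out / "target_correlations.tsv"), sep="\t")
                tc.top_t0.to_csv(record(out / "top_t0.tsv"), sep="\t")
                tc.top_t1.to_csv(record(out / "top_t1.tsv"), sep="\t")
                tc.top_delta.to_csv(record(out / "top_delta.tsv"), sep="\t")
                tc.questionnaire_medians.to_csv(
                    record(out / "questionnaire_medians.tsv"), sep="\t"
                )
            elif stage == "select":
                X, y, _ = get_xy()
                traces = []
                for spec in config.classifier_specs():
                    trace = run_ife(
                        X, y, spec,
                        k=config.cv_folds,
                        n_perm=config.n_perm,
                        master_seed=config.seed,
                        max_iter=config.max_iter,
                    )
                    traces.append(trace)
                    path = record(out / f"trace_{spec.algorithm}.json")
                    path.write_text(json.dumps(
                        {
                            "classifier": trace.classifier,
                            "termination_reason": trace.termination_reason,
                            "iterations": trace.to_records(),
                        }, indent=1,
                    ))
                matrix = _elimination_matrix(traces)
                matrix.to_csv(record(out / "elimination_matrix.tsv"), sep="\t")
                clf, iteration, cv, feats = select_best(traces)
                best = {
                    "classifier": clf,
                    "iteration": iteration,
                    "mean_auc": cv.mean_auc,
                    "sd_auc": cv.sd_auc,
                    "ci95": list(cv.ci95),
                    "params": cv.params,
                    "features": feats,
                }
                record(out / "best_model.json").write_text(
                    json.dumps(best, indent=1)
                )
                scores = _positive_proba(cv.model, X[feats])
                tm = threshold_metrics(scores, y, 0.5)
                record(out / "threshold_metrics.json").write_text(
                    json.dumps(
                        {
                            "threshold": tm.threshold,
                            "accuracy": tm.accuracy,
                            "sensitivity": tm.sensitivity,
                            "specificity": tm.specificity,
                            "precision": tm.precision,
                            "npv": tm.npv,
                        }, indent=1,
                    )
                )
            elif stage == "explain":
                X, y, _ = get_xy()
                best = json.loads((out / "best_model.json").read_text())
                feats = best["features"]
                model = make_estimator(best["classifier"],
                                       seed=config.seed + _SEED_CV)
                _set_params(model, best["classifier"], best["params"])
                model.fit(X[feats], y)
                attr = compute_attributions(
                    model, X[feats], seed=config.seed
                )
                phi = attr.phi.copy()
                phi["phi0"] = attr.phi0
                phi.to_csv(record(out / "attributions.csv"))
                ranking = global_importance(attr)
                ranking.table.to_csv(
                    record(out / "importance.tsv"), sep="\t", index=False
                )
                k = min(config.explain_clusters, attr.n_instances)
                clusters = cluster_explanations(attr, k)
                pd.DataFrame(
                    {"patient": attr.phi.index, "cluster": clusters.labels}
                ).to_csv(record(out / "explanation_clusters.tsv"),
                         sep="\t", index=False)
                for feat in ranking.ranked_features[: config.n_dependence_profiles]:
                    prof = dependence_profile(attr, X[feats], feat)
                    prof.to_csv(
                        record(out / f"dependence_{feat}.tsv"),
                        sep="\t", index=False,
                    )
                top = ranking.ranked_features[: config.marginal_curve_max]
                curve = marginal_importance_curve(
                    X, y, top,
                    ClassifierSpec(best["classifier"],
                                   {p: [v] for p, v in best["params"].items()}),
                    k=config.cv_folds,
                    seed=config.seed + _SEED_CV,
                )
                curve.to_csv(record(out / "marginal_curve.tsv"),
                             sep="\t", index=False)
                rho_sel = spearman_matrix(X[feats]) if len(feats) > 1 else None
                if rho_sel is not None:
                    edges, components = correlation_network(
                        rho_sel, config.network_threshold
                    )
                else:
                    edges, components = [], []
                record(out / "network.json").write_text(json.dumps(
                    {
                        "threshold": config.network_threshold,
                        "edges": edges,
                        "components": components,
                    }, indent=1,
                ))
            elif stage == "report":
                manifest = {
                    "config_hash": config.canonical_hash(),
                    "seed": config.seed,
                    "version": __version__,
                    "files": sorted(set(files)),
                }
                manifest_path.write_text(json.dumps(manifest, indent=1))
                for name in manifest["files"]:
                    path = out / name
                    if not path.exists() or path.stat().st_size == 0:
                        raise RuntimeError(f"manifest lists missing/empty {name}")
    except StageError:
        raise
    except BaseException as exc:
        partial = {
            "config_hash": config.canonical_hash(),
            "seed": config.seed,
            "version": __version__,
            "failed_stage": stage,
            "files": sorted(set(files)),
        }
        manifest_path.write_text(json.dumps(partial, indent=1))
        raise StageError(stage, exc) from exc

    manifest = json.loads(manifest_path.read_text()) if manifest_path.exists() \
        else {"files": sorted(set(files)), "seed": config.seed}
    return ReportBundle(out_dir=out, manifest=manifest)


def _spec_from_config(config: RunConfig) -> SyntheticSpec:
    d = dict(config.synthetic)
    d.setdefault("seed", config.seed)
    from .synthetic import BlockSpec, InformativeEffect

    blocks = [
        BlockSpec(**b) if isinstance(b, dict) else BlockSpec(*b)
        for b in d.pop("block_specs", [])
    ]
    informative = tuple(
        InformativeEffect(**e) if isinstance(e, dict) else InformativeEffect(*e)
        for e in d.pop("informative_features", [])
    )
    return SyntheticSpec(
        block_specs=blocks, informative_features=informative, **d
    )
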