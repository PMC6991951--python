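"""Seeded synthetic questionnaire cohorts.

The generator emulates the statistical skeleton of a multi-questionnaire
tinnitus cohort: two large anti-correlated blocks of Likert items
(negatively vs positively polarized scales), per-questionnaire completion
times, dichotomous sociodemographics, planted linear and J-shaped effects on
a continuous distress score in [0, 84], and a target class prevalence after
discretizing that score at a cutoff.

Latent structure
----------------
Each block feature is a unit-variance Gaussian

    x = s_b * sqrt(g) * W  +  sqrt(rho_b - g) * G_b  +  sqrt(1 - rho_b) * e

where ``W`` is a cohort-wide factor, ``G_b`` a block factor, ``e`` an
idiosyncratic term, ``rho_b`` the within-block correlation, ``g`` the
magnitude of the between-block correlation and ``s_b`` the block polarity
sign.  Within-block correlation is exactly ``rho_b``; the correlation
between features of opposite polarity is ``-g``.  Latents are then mapped to
the declared scale types (equal-probability quantile bins for Likert items,
a zero threshold for dichotomous items, a log-normal map for completion
times), which preserves rank correlation up to discretization loss.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BlockSpec",
    "InformativeEffect",
    "SyntheticSpec",
    "FeatureMeta",
    "CohortTable",
    "generate_cohort",
    "plant_outcome",
    "j_shape",
    "write_cohort",
    "read_cohort",
    "study_like_spec",
]

SCORE_MAX = 84.0
DEFAULT_CUTOFF = 46.0

# Fixed child-seed offsets for the independent random streams.
_SEED_LATENT = 11
_SEED_OUTCOME = 23
_SEED_T0 = 37


class SpecError(ValueError):
    """A synthetic-cohort specification violates one of its invariants."""


@dataclass(frozen=True)
class BlockSpec:
    size: int
    polarity: Literal["negative", "positive"]
    intra_rho: float


@dataclass(frozen=True)
class InformativeEffect:
    """A planted feature -> outcome effect.

    ``shape`` is either ``linear`` (identity link) or ``j_shaped`` (dip then
    rise; see :func:`j_shape`).
    """

    index: int
    coefficient: float
    shape: Literal["linear", "j_shaped"] = "linear"


@dataclass(frozen=True)
class SyntheticSpec:
    n_patients: int
    block_specs: Sequence[BlockSpec]
    inter_block_rho: float = -0.3
    n_noise_features: int = 0
    informative_features: Sequence[InformativeEffect] = ()
    likert_levels: int = 5
    n_dichotomous: int = 0
    n_timestamp: int = 0
    target_prevalence: float = 0.32
    noise_sd: float = 1.0
    seed: int = 0
    t0_shift_mean: float = 6.0
    t0_shift_sd: float = 4.0

    @property
    def n_features(self) -> int:
        return (
            sum(b.size for b in self.block_specs)
            + self.n_noise_features
            + self.n_dichotomous
            + self.n_timestamp
        )

    def validate(self) -> None:
        if self.n_patients < 1:
            raise SpecError("n_patients must be positive")
        if not self.block_specs and self.n_features == 0:
            raise SpecError("spec describes zero features")
        for b in self.block_specs:
            if b.size < 1:
                raise SpecError(f"block size must be positive, got {b.size}")
            if not (0.0 <= b.intra_rho < 1.0):
                raise SpecError(f"intra_rho must be in [0, 1), got {b.intra_rho}")
            if b.polarity not in ("negative", "positive"):
                raise SpecError(f"unknown polarity {b.polarity!r}")
            if b.intra_rho < abs(self.inter_block_rho):
                raise SpecError(
                    "intra_rho must be >= |inter_block_rho| "
                    f"({b.intra_rho} < {abs(self.inter_block_rho)})"
                )
        if not (-1.0 < self.inter_block_rho <= 0.0):
            raise SpecError(
                f"inter_block_rho must be in (-1, 0], got {self.inter_block_rho}"
            )
        if min(self.n_noise_features, self.n_dichotomous, self.n_timestamp) < 0:
            raise SpecError("feature counts must be nonnegative")
        if self.likert_levels < 2:
            raise SpecError(f"likert_levels must be >= 2, got {self.likert_levels}")
        if not (0.0 < self.target_prevalence < 1.0):
            raise SpecError(
                f"target_prevalence must be in (0, 1), got {self.target_prevalence}"
            )
        if self.noise_sd < 0:
            raise SpecError(f"noise_sd must be nonnegative, got {self.noise_sd}")
        p = self.n_features
        for eff in self.informative_features:
            if not (0 <= eff.index < p):
                raise SpecError(
                    f"informative feature index {eff.index} outside [0, {p})"
                )
            if not np.isfinite(eff.coefficient):
                raise SpecError("informative coefficient must be finite")
            if eff.shape not in ("linear", "j_shaped"):
                raise SpecError(f"unknown effect shape {eff.shape!r}")


@dataclass(frozen=True)
class FeatureMeta:
    name: str
    group: str
    scale: Literal["likert", "dichotomous", "continuous", "timestamp"]


@dataclass
class CohortTable:
    """Patient x feature table with outcome scores at both time points."""

    patient_ids: list[str]
    features: pd.DataFrame
    feature_meta: list[FeatureMeta]
    tq_t0: np.ndarray
    tq_t1: np.ndarray
    spec: SyntheticSpec | None = None

    @property
    def n_patients(self) -> int:
        return len(self.patient_ids)

    @property
    def feature_names(self) -> list[str]:
        return list(self.features.columns)

    def validate(self, likert_levels: int | None = None) -> None:
        if self.features.isna().any().any():
            raise ValueError("cohort table contains missing values")
        if len(self.feature_meta) != self.features.shape[1]:
            raise ValueError("feature_meta length does not match feature count")
        for meta in self.feature_meta:
            col = self.features[meta.name].to_numpy()
            if meta.scale == "likert":
                if not np.array_equal(col, np.round(col)):
                    raise ValueError(f"likert column {meta.name} is not integral")
                if col.min() < 0:
                    raise ValueError(f"likert column {meta.name} has negative levels")
                if likert_levels is not None and col.max() > likert_levels - 1:
                    raise ValueError(f"likert column {meta.name} exceeds level range")
            elif meta.scale == "dichotomous":
                if not np.isin(col, (0.0, 1.0)).all():
                    raise ValueError(f"dichotomous column {meta.name} not in {{0,1}}")
            elif meta.scale == "timestamp":
                if col.min() < 0:
                    raise ValueError(f"timestamp column {meta.name} is negative")
        for arr, label in ((self.tq_t0, "tq_t0"), (self.tq_t1, "tq_t1")):
            if arr.min() < 0 or arr.max() > SCORE_MAX:
                raise ValueError(f"{label} outside [0, {SCORE_MAX}]")


def j_shape(values: np.ndarray, low: float, high: float) -> np.ndarray:
    """Dip-then-rise link on the range [low, high].

    The minimum sits at 30% of the range: mild rise toward the low end,
    strong quadratic rise toward the high end (on a 0-10 scale the dip is
    near 3).
    """
    v = np.asarray(values, dtype=float) - low
    r = high - low
    if r <= 0:
        raise ValueError("j_shape requires a feature with positive range")
    return (v - 0.3 * r) ** 2 / r**2 + 0.15 * np.maximum(0.0, 0.3 * r - v) / r


def _rescale_to_scores(raw: np.ndarray, target_prevalence: float,
                       cutoff: float = DEFAULT_CUTOFF) -> np.ndarray:
    """Monotone piecewise-linear map of ``raw`` onto [0, 84].

    The (1 - prevalence) sample quantile is sent to ``cutoff`` so that the
    fraction of scores strictly above the cutoff matches the target up to
    the granularity of the sample.
    """
    lo, hi = float(raw.min()), float(raw.max())
    t = float(np.quantile(raw, 1.0 - target_prevalence))
    if not (lo < t < hi):
        raise ValueError(
            "outcome predictor is too degenerate to calibrate prevalence "
            "(constant or single-sided linear predictor)"
        )
    scores = np.where(
        raw <= t,
        cutoff * (raw - lo) / (t - lo),
        cutoff + (SCORE_MAX - cutoff) * (raw - t) / (hi - t),
    )
    return np.clip(scores, 0.0, SCORE_MAX)


def plant_outcome(
    features: pd.DataFrame | np.ndarray,
    informative_features: Sequence[InformativeEffect],
    noise_sd: float,
    target_prevalence: float,
    seed: int,
    t0_shift_mean: float = 6.0,
    t0_shift_sd: float = 4.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Build (tq_t0, tq_t1) distress scores from planted feature effects.

    The linear predictor sums coefficient * g(feature) over the informative
    features (g identity for linear effects, the J-shape link otherwise), is
    standardized, and Gaussian noise of sd ``noise_sd`` is added.  The noisy
    predictor is monotonically rescaled to [0, 84] so that the fraction of
    T1 scores above the cutoff 46 matches ``target_prevalence``.  T0 is T1
    plus an independent positive offset (treatment lowers distress on
    average), clipped to the score range.
    """
    X = np.asarray(features, dtype=float)
    n = X.shape[0]
    rng_outcome = np.random.default_rng(seed + _SEED_OUTCOME)
    rng_t0 = np.random.default_rng(seed + _SEED_T0)

    lp = np.zeros(n)
    for eff in informative_features:
        col = X[:, eff.index]
        if eff.shape == "linear":
            g = col
        else:
            g = j_shape(col, float(col.min()), float(col.max()))
        lp = lp + eff.coefficient * g
    sd = lp.std()
    if sd > 0:
        lp = (lp - lp.mean()) / sd
    raw = lp + rng_outcome.normal(0.0, noise_sd, size=n)
    if raw.std() == 0:
        raise ValueError(
            "cannot plant outcome: zero-variance predictor "
            "(no informative effects and noise_sd = 0)"
        )
    tq_t1 = _rescale_to_scores(raw, target_prevalence)
    delta = np.abs(rng_t0.normal(t0_shift_mean, t0_shift_sd, size=n))
    tq_t0 = np.clip(tq_t1 + delta, 0.0, SCORE_MAX)
    return tq_t0, tq_t1


# Questionnaire-style group labels cycled over generated features so the
# correlation analytics have a realistic membership structure to aggregate.
_NEG_GROUPS = ("ADSL", "BI", "BSF", "PSQ", "TINSKAL", "TLQ")
_POS_GROUPS = ("SF8", "SWOP")


def _latent_matrix(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    n, p = spec.n_patients, spec.n_features
    Z = np.empty((n, p))
    g = abs(spec.inter_block_rho)
    W = rng.standard_normal(n)
    col = 0
    for b in spec.block_specs:
        G = rng.standard_normal(n)
        s = 1.0 if b.polarity == "positive" else -1.0
        eps = rng.standard_normal((n, b.size))
        Z[:, col : col + b.size] = (
            s * np.sqrt(g) * W[:, None]
            + np.sqrt(b.intra_rho - g) * G[:, None]
            + np.sqrt(1.0 - b.intra_rho) * eps
        )
        col += b.size
    n_rest = spec.n_noise_features + spec.n_dichotomous + spec.n_timestamp
    if n_rest:
        Z[:, col:] = rng.standard_normal((n, n_rest))
    return Z


def generate_cohort(spec: SyntheticSpec) -> CohortTable:
    """Generate a seeded cohort honoring ``spec``.

    Raises :class:`SpecError` naming the violated invariant for an invalid
    spec.  Identical (spec, seed) produce bit-identical tables.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed + _SEED_LATENT)
    Z = _latent_matrix(spec, rng)

    cols: dict[str, np.ndarray] = {}
    meta: list[FeatureMeta] = []
    col = 0
    for bi, b in enumerate(spec.block_specs):
        groups = _NEG_GROUPS if b.polarity == "negative" else _POS_GROUPS
        for j in range(b.size):
            group = groups[j % len(groups)]
            name = f"{group}_b{bi}_item{j:03d}"
            u = stats.norm.cdf(Z[:, col])
            levels = np.minimum(
                np.floor(u * spec.likert_levels), spec.likert_levels - 1
            )
            cols[name] = levels
            meta.append(FeatureMeta(name, group, "likert"))
            col += 1
    for j in range(spec.n_noise_features):
        name = f"NOISE_item{j:03d}"
        cols[name] = Z[:, col]
        meta.append(FeatureMeta(name, "NOISE", "continuous"))
        col += 1
    for j in range(spec.n_dichotomous):
        name = f"SOZK_dich{j:03d}"
        cols[name] = (Z[:, col] > 0).astype(float)
        meta.append(FeatureMeta(name, "SOZK", "dichotomous"))
        col += 1
    for j in range(spec.n_timestamp):
        name = f"Q{j:02d}_timestamp"
        cols[name] = np.exp(3.0 + 0.5 * Z[:, col])
        meta.append(FeatureMeta(name, "TIMESTAMP", "timestamp"))
        col += 1

    features = pd.DataFrame(cols)
    tq_t0, tq_t1 = plant_outcome(
        features,
        spec.informative_features,
        spec.noise_sd,
        spec.target_prevalence,
        spec.seed,
        spec.t0_shift_mean,
        spec.t0_shift_sd,
    )
    ids = [f"P{i:05d}" for i in range(spec.n_patients)]
    cohort = CohortTable(ids, features, meta, tq_t0, tq_t1, spec=spec)
    cohort.validate(spec.likert_levels)
    return cohort


def study_like_spec(seed: int = 0, n_patients: int = 1416) -> SyntheticSpec:
    """A cohort spec mirroring the study conditions.

    1,416 patients, 205 features: a 114-feature negatively polarized block
    and a 47-feature positively polarized block of 5-level Likert items with
    moderate within-block correlation and negative between-block
    correlation, 10 per-questionnaire completion-time features, 26
    dichotomous sociodemographic indicators and 8 unstructured continuous
    features; ~32% decompensated prevalence at T1 with linear and J-shaped
    planted effects.
    """
    blocks = [
        BlockSpec(114, "negative", 0.45),
        BlockSpec(47, "positive", 0.45),
    ]
    informative = (
        InformativeEffect(0, 1.0, "j_shaped"),    # impairment-like item
        InformativeEffect(1, 0.8, "linear"),      # depression-like item
        InformativeEffect(2, 0.5, "linear"),
        InformativeEffect(114, -0.6, "linear"),   # positive-block protective
        InformativeEffect(115, -0.4, "linear"),
        InformativeEffect(195, 0.4, "j_shaped"),  # a completion-time feature
        InformativeEffect(175, 0.3, "linear"),    # a dichotomous indicator
    )
    return SyntheticSpec(
        n_patients=n_patients,
        block_specs=blocks,
        inter_block_rho=-0.3,
        n_noise_features=8,
        informative_features=informative,
        likert_levels=5,
        n_dichotomous=26,
        n_timestamp=10,
        target_prevalence=0.32,
        noise_sd=0.8,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# CSV + JSON sidecar round-trip


def write_cohort(cohort: CohortTable, prefix: str | Path) -> tuple[Path, Path]:
    """Write ``<prefix>.csv`` (one row per patient) and ``<prefix>.meta.json``."""
    prefix = Path(prefix)
    csv_path = prefix.with_suffix(".csv")
    meta_path = prefix.with_suffix(".meta.json")
    df = cohort.features.copy()
    df.insert(0, "patient_id", cohort.patient_ids)
    df["tq_t0"] = cohort.tq_t0
    df["tq_t1"] = cohort.tq_t1
    df.to_csv(csv_path, index=False)
    sidecar = {
        "feature_meta": [
            {"name": m.name, "group": m.group, "scale": m.scale}
            for m in cohort.feature_meta
        ],
        "spec": _spec_to_dict(cohort.spec) if cohort.spec is not None else None,
    }
    meta_path.write_text(json.dumps(sidecar, indent=1))
    return csv_path, meta_path


def read_cohort(prefix: str | Path) -> CohortTable:
    """Load a cohort written by :func:`write_cohort` (bit-exact round trip)."""
    prefix = Path(prefix)
    df = pd.read_csv(prefix.with_suffix(".csv"), float_precision="round_trip")
    sidecar = json.loads(prefix.with_suffix(".meta.json").read_text())
    meta = [FeatureMeta(**m) for m in sidecar["feature_meta"]]
    ids = df["patient_id"].astype(str).tolist()
    tq_t0 = df["tq_t0"].to_numpy(dtype=float)
    tq_t1 = df["tq_t1"].to_numpy(dtype=float)
    features = df.drop(columns=["patient_id", "tq_t0", "tq_t1"])
    spec = _spec_from_dict(sidecar["spec"]) if sidecar.get("spec") else None
    return CohortTable(ids, features, meta, tq_t0, tq_t1, spec=spec)


def _spec_to_dict(spec: SyntheticSpec) -> dict:
    return {
        "n_patients": spec.n_patients,
        "block_specs": [
            {"size": b.size, "polarity": b.polarity, "intra_rho": b.intra_rho}
            for b in spec.block_specs
        ],
        "inter_block_rho": spec.inter_block_rho,
        "n_noise_features": spec.n_noise_features,
        "informative_features": [
            {"index": e.index, "coefficient": e.coefficient, "shape": e.shape}
            for e in spec.informative_features
        ],
        "likert_levels": spec.likert_levels,
        "n_dichotomous": spec.n_dichotomous,
        "n_timestamp": spec.n_timestamp,
        "target_prevalence": spec.target_prevalence,
        "noise_sd": spec.noise_sd,
        "seed": spec.seed,
        "t0_shift_mean": spec.t0_shift_mean,
        "t0_shift_sd": spec.t0_shift_sd,
    }


def _spec_from_dict(d: dict) -> SyntheticSpec:
    return SyntheticSpec(
        n_patients=d["n_patients"],
        block_specs=[BlockSpec(**b) for b in d["block_specs"]],
        inter_block_rho=d["inter_block_rho"],
        n_noise_features=d["n_noise_features"],
        informative_features=tuple(
            InformativeEffect(e["index"], e["coefficient"], e["shape"])
            for e in d["informative_features"]
        ),
        likert_levels=d["likert_levels"],
        n_dichotomous=d["n_dichotomous"],
        n_timestamp=d["n_timestamp"],
        target_prevalence=d["target_prevalence"],
        noise_sd=d["noise_sd"],
        seed=d["seed"],
        t0_shift_mean=d.get("t0_shift_mean", 6.0),
        t0_shift_sd=d.get("t0_shift_sd", 4.0),
    )
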