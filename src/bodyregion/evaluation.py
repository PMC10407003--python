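"""Metrics, confusion matrices, spatially aware bootstrap CIs, and audits.

Slices within a series are strongly correlated (they are millimetres apart),
so naive per-image confidence intervals are far too narrow.  The bootstrap
here resamples *studies* with replacement, keeps one randomly chosen series
per study, and subsamples each kept series so that no two slices are closer
than a minimum physical spacing (default 10 mm, also respecting slice
thickness).  Weighted F1 / sensitivity / specificity are recorded per
iteration and percentile confidence intervals reported.

Association between classification accuracy and confounding factors
(manufacturer, contrast, slice thickness, ...) is quantified with Pearson's
chi-squared test and Cramér's V effect size on the correct/incorrect × factor
contingency table.  A DICOM-tag audit measures how often free-text
BodyPartExamined / ProcedureType values agree with the image-derived study
regions.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, field_validator
from scipy import stats

from .postprocess import PredictionSequence

logger = logging.getLogger(__name__)


@dataclass
class ConfusionMatrix:
    """K×K counts; rows are predictions, columns are ground truth."""

    counts: np.ndarray
    class_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.class_names)
        if self.counts.shape != (k, k):
            raise ValueError("counts must be square and match class_names")
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")

    @classmethod
    def empty(cls, class_names: Sequence[str]) -> "ConfusionMatrix":
        k = len(class_names)
        return cls(np.zeros((k, k), dtype=np.int64), tuple(class_names))

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.class_names), columns=list(self.class_names))


def accumulate_confusion(
    predictions: Sequence[PredictionSequence],
    truth: Mapping[str, str],
    class_names: Sequence[str],
) -> ConfusionMatrix:
    """Tally one increment per evaluated image at [predicted, true].

    Indeterminate (below-threshold) slices and slices without ground truth are
    skipped; a predicted or true label outside ``class_names`` is an error.
    """
    index = {name: i for i, name in enumerate(class_names)}
    cm = ConfusionMatrix.empty(class_names)
    for seq in predictions:
        labels = seq.labels()
        for (z, pred), label in zip(seq.entries, labels):
            if pred.indeterminate:
                continue
            true = truth.get(pred.image_uid)
            if true is None:
                continue
            if label not in index:
                raise ValueError(f"predicted label {label!r} outside vocabulary")
            if true not in index:
                raise ValueError(f"truth label {true!r} outside vocabulary")
            cm.counts[index[label], index[true]] += 1
    return cm


@dataclass(frozen=True)
class ClassMetrics:
    f1: float
    sensitivity: float
    specificity: float
    support: int


@dataclass
class MetricReport:
    """Per-class and support-weighted one-vs-rest metrics, optionally with CIs."""

    per_class: dict[str, ClassMetrics]
    weighted_f1: float
    weighted_sensitivity: float
    weighted_specificity: float
    n_evaluated: int
    cis: dict[str, tuple[float, float]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "weighted_f1": self.weighted_f1,
            "weighted_sensitivity": self.weighted_sensitivity,
            "weighted_specificity": self.weighted_specificity,
            "n_evaluated": self.n_evaluated,
            "cis": {k: list(v) for k, v in self.cis.items()},
            "per_class": {
                name: {
                    "f1": m.f1,
                    "sensitivity": m.sensitivity,
                    "specificity": m.specificity,
                    "support": m.support,
                }
                for name, m in self.per_class.items()
            },
        }


def compute_metrics(cm: ConfusionMatrix) -> MetricReport:
    """Per-class one-vs-rest F1/sensitivity/specificity and support-weighted means.

    Sensitivity = TP/(TP+FN), specificity = TN/(TN+FP), F1 = 2PR/(P+R); weights
    are the true-class supports (column sums).  Classes with no ground-truth
    support have undefined sensitivity and are excluded from the weighting with
    a warning.
    """
    if cm.total == 0:
        raise ValueError("confusion matrix is empty")
    counts = cm.counts.astype(float)
    n = counts.sum()
    tp = np.diag(counts)
    col = counts.sum(axis=0)  # truth support
    row = counts.sum(axis=1)  # prediction totals
    fn = col - tp
    fp = row - tp
    tn = n - tp - fn - fp

    per_class: dict[str, ClassMetrics] = {}
    weights, sens_list, spec_list, f1_list = [], [], [], []
    for k, name in enumerate(cm.class_names):
        if col[k] == 0:
            if row[k] > 0:
                logger.warning("class %s has predictions but no ground truth; excluded from weighting", name)
            continue
        sens = tp[k] / (tp[k] + fn[k])
        spec = tn[k] / (tn[k] + fp[k]) if (tn[k] + fp[k]) > 0 else float("nan")
        precision = tp[k] / row[k] if row[k] > 0 else 0.0
        f1 = 2 * precision * sens / (precision + sens) if (precision + sens) > 0 else 0.0
        per_class[name] = ClassMetrics(f1=f1, sensitivity=sens, specificity=spec, support=int(col[k]))
        weights.append(col[k])
        sens_list.append(sens)
        spec_list.append(spec)
        f1_list.append(f1)
    w = np.asarray(weights) / sum(weights)
    return MetricReport(
        per_class=per_class,
        weighted_f1=float(w @ np.asarray(f1_list)),
        weighted_sensitivity=float(w @ np.asarray(sens_list)),
        weighted_specificity=float(w @ np.asarray(spec_list)),
        n_evaluated=int(n),
    )


class BootstrapConfig(BaseModel):
    n_iterations: int = 1000
    min_spacing_mm: float = 10.0
    series_per_study: int = 1
    ci_level: float = 0.95
    seed: int = 0

    @field_validator("min_spacing_mm")
    @classmethod
    def _spacing(cls, v):
        if v <= 0:
            raise ValueError("spacing must be positive")
        return v

    @field_validator("ci_level")
    @classmethod
    def _level(cls, v):
        if not 0 < v < 1:
            raise ValueError("ci_level must be in (0, 1)")
        return v


def spatial_sample(
    z_positions: Sequence[float],
    min_spacing_mm: float,
    rng: np.random.Generator,
    slice_thickness: float = 0.0,
) -> np.ndarray:
    """Indices of a spatially decorrelated subsample of a sorted slice stack.

    Greedy scan from a randomly offset start: a slice is kept only if it is at
    least ``max(min_spacing_mm, slice_thickness)`` from the last kept slice,
    guaranteeing all pairwise kept distances meet the minimum spacing.
    """
    z = np.asarray(z_positions, dtype=float)
    if z.size == 0:
        return np.array([], dtype=int)
    if np.any(np.diff(z) < 0):
        raise ValueError("z_positions must be sorted ascending")
    gap = max(min_spacing_mm, slice_thickness)
    offset = rng.uniform(0.0, gap)
    threshold = z[0] + offset
    kept = []
    # the offset start may skip everything; fall back to a plain greedy scan
    first = int(np.searchsorted(z, threshold))
    if first >= z.size:
        first = 0
    last = -np.inf
    for i in range(first, z.size):
        if z[i] - last >= gap or not kept:
            kept.append(i)
            last = z[i]
    return np.asarray(kept, dtype=int)


@dataclass
class _SeriesArrays:
    """Flattened arrays of one evaluated series for fast bootstrap iterations."""

    z: np.ndarray
    pred: np.ndarray
    true: np.ndarray
    valid: np.ndarray
    thickness: float


def _prepare_series(
    seq: PredictionSequence,
    truth: Mapping[str, str],
    index: Mapping[str, int],
    slice_thickness: float,
) -> _SeriesArrays:
    z, pred, true, valid = [], [], [], []
    labels = seq.labels()
    for (zpos, p), label in zip(seq.entries, labels):
        z.append(zpos)
        pred.append(index.get(label, -1))
        t = truth.get(p.image_uid)
        true.append(index.get(t, -1) if t is not None else -1)
        valid.append((not p.indeterminate) and t is not None and label in index)
    return _SeriesArrays(
        z=np.asarray(z), pred=np.asarray(pred), true=np.asarray(true),
        valid=np.asarray(valid, dtype=bool), thickness=slice_thickness,
    )


def bootstrap_ci(
    studies: Sequence[Sequence[PredictionSequence]],
    truth: Mapping[str, str],
    class_names: Sequence[str],
    cfg: Optional[BootstrapConfig] = None,
    slice_thickness: Mapping[str, float] | float = 0.0,
) -> MetricReport:
    """Spatially aware bootstrap of the weighted metrics.

    Each iteration resamples studies with replacement, keeps one randomly
    selected series per study, spatially subsamples its slices, accumulates a
    confusion matrix and records the weighted metrics; the CI is the percentile
    interval over iterations.  The returned report's point estimates come from
    the full (unsampled) cohort; ``cis`` holds the bootstrap intervals.
    """
    cfg = cfg or BootstrapConfig()
    if cfg.n_iterations < 10:
        raise ValueError("n_iterations must be >= 10")
    if not studies:
        raise ValueError("empty cohort")
    index = {name: i for i, name in enumerate(class_names)}
    k = len(class_names)

    def _thickness(seq: PredictionSequence) -> float:
        if isinstance(slice_thickness, Mapping):
            return float(slice_thickness.get(seq.series_uid, 0.0))
        return float(slice_thickness)

    prepared = [
        [_prepare_series(seq, truth, index, _thickness(seq)) for seq in study]
        for study in studies
    ]
    all_seqs = [seq for study in studies for seq in study]
    point = compute_metrics(accumulate_confusion(all_seqs, truth, class_names))

    rng = np.random.default_rng(cfg.seed)
    n = len(prepared)
    alpha = (1.0 - cfg.ci_level) / 2.0
    samples = {"weighted_f1": [], "weighted_sensitivity": [], "weighted_specificity": []}
    for _ in range(cfg.n_iterations):
        counts = np.zeros((k, k), dtype=np.int64)
        for study_idx in rng.integers(0, n, size=n):
            study = prepared[study_idx]
            picks = rng.choice(len(study), size=min(cfg.series_per_study, len(study)), replace=False)
            for s_idx in picks:
                sa = study[s_idx]
                kept = spatial_sample(sa.z, cfg.min_spacing_mm, rng, sa.thickness)
                kept = kept[sa.valid[kept]]
                np.add.at(counts, (sa.pred[kept], sa.true[kept]), 1)
        if counts.sum() == 0:
            continue
        rep = compute_metrics(ConfusionMatrix(counts, tuple(class_names)))
        samples["weighted_f1"].append(rep.weighted_f1)
        samples["weighted_sensitivity"].append(rep.weighted_sensitivity)
        samples["weighted_specificity"].append(rep.weighted_specificity)
    point.cis = {
        key: (
            float(np.percentile(vals, 100 * alpha)),
            float(np.percentile(vals, 100 * (1 - alpha))),
        )
        for key, vals in samples.items()
        if vals
    }
    return point


@dataclass(frozen=True)
class AssociationResult:
    factor: str
    cramers_v: float
    chi2: float
    p_value: float
    dof: int
    n: int


def association(
    correct_flags: Sequence[bool],
    factor_levels: Sequence[str],
    factor_name: str = "factor",
) -> AssociationResult:
    """Pearson chi-squared test and Cramér's V for accuracy vs a categorical factor.

    The contingency table is correct/incorrect × factor level;
    V = sqrt(χ² / (n·(min(r, c) − 1))).
    """
    if len(correct_flags) != len(factor_levels) or len(correct_flags) == 0:
        raise ValueError("correct_flags and factor_levels must be nonempty and aligned")
    table = pd.crosstab(pd.Series(correct_flags, name="correct"), pd.Series(factor_levels, name="level"))
    table = table.loc[:, table.sum(axis=0) > 0]
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("degenerate contingency table: need >=2 outcome rows and >=2 factor levels")
    chi2, p, dof, _ = stats.chi2_contingency(table.to_numpy(), correction=False)
    n = int(table.to_numpy().sum())
    v = float(np.sqrt(chi2 / (n * (min(table.shape) - 1))))
    return AssociationResult(factor_name, v, float(chi2), float(p), int(dof), n)


#: Free-text tag value → vocabulary region; extend per site.
DEFAULT_TAG_MAP: dict[str, str] = {
    "HEAD": "head", "BRAIN": "head", "SKULL": "head",
    "NECK": "neck",
    "CHEST": "chest", "THORAX": "chest", "LUNG": "chest",
    "BREAST": "breast",
    "ABDOMEN": "abdomen", "LIVER": "abdomen",
    "PELVIS": "pelvis_hip", "HIP": "pelvis_hip",
    "THIGH": "thigh", "FEMUR": "thigh",
    "KNEE": "knee",
    "CALF": "calf", "LOWER LEG": "calf", "TIBIA": "calf",
    "FOOT": "foot", "ANKLE": "foot",
    "SHOULDER": "shoulder",
    "ARM": "arm", "HUMERUS": "arm", "UPPER ARM": "arm",
    "ELBOW": "elbow",
    "FOREARM": "forearm",
    "HAND": "hand", "WRIST": "hand",
    "CSPINE": "spine_cervical", "CERVICAL SPINE": "spine_cervical",
    "TSPINE": "spine_thoracic", "THORACIC SPINE": "spine_thoracic",
    "LSPINE": "spine_lumbar", "LUMBAR SPINE": "spine_lumbar", "LSSPINE": "spine_lumbar",
}


def audit_dicom_tags(
    tag_values: Mapping[str, Mapping[str, str]],
    truth_regions: Mapping[str, set[str]],
    tag_map: Optional[Mapping[str, str]] = None,
) -> dict[str, float]:
    """Accuracy of free-text DICOM body-part tags against image-derived regions.

    ``tag_values`` maps tag name → (study uid → raw tag string).  A study
    counts as accurate for a tag iff the mapped region is among the study's
    ground-truth regions; empty or unmapped values are inaccurate.  Returns
    percentage accuracy per tag, one decimal.
    """
    mapping = {k.upper(): v for k, v in (tag_map or DEFAULT_TAG_MAP).items()}
    out: dict[str, float] = {}
    for tag, values in tag_values.items():
        n = accurate = 0
        for study_uid, regions in truth_regions.items():
            n += 1
            raw = (values.get(study_uid) or "").strip().upper()
            region = mapping.get(raw)
            if region is not None and region in regions:
                accurate += 1
        out[tag] = round(100.0 * accurate / n, 1) if n else 0.0
    return out


def write_report(
    report: MetricReport,
    cm: ConfusionMatrix,
    out_dir: "str | Path",
    associations: Sequence[AssociationResult] = (),
) -> None:
    """Write the evaluation artifacts: metrics JSON, confusion CSV, association CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "metrics.json").write_text(json.dumps(report.to_dict(), indent=2))
    cm.to_frame().to_csv(out / "confusion_matrix.csv")
    if associations:
        pd.DataFrame(
            [
                {"factor": a.factor, "cramers_v": a.cramers_v, "chi2": a.chi2,
                 "p_value": a.p_value, "dof": a.dof, "n": a.n}
                for a in associations
            ]
        ).to_csv(out / "associations.csv", index=False)
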