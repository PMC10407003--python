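"""Series-level rule engine and smoothing applied after the slice classifier.

A series is a spatially ordered stack, so neighbouring slices should carry
consistent labels.  Five stages run in a fixed order on the per-slice class
probability sequence:

1. merge the transitional abdomen-chest class into abdomen or chest,
   whichever is predominant in the series (abdomen when neither occurs);
2. classify the whole series as breast when at least 50% of its slices are
   (MRI only — eliminates spurious labels in noisy breast acquisitions);
3. remove outlier labels: an isolated slice whose two flanking labels agree
   is replaced by the flanking label, iterated to a fixed point;
4. smooth with a centred moving-average filter of window 3 over the per-class
   probability sequences (truncated at the edges), re-taking the argmax;
5. mark slices whose confidence falls below 0.5 as indeterminate, excluding
   them from confusion-matrix accumulation.

A moving average over categorical labels is undefined, so every stage is
expressed as a transformation of the probability vectors (mass reassignment,
one-hot override, flank averaging); labels are always the argmax of the
current vector, which keeps the stages composable and the smoothing unable to
resurrect a merged class.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from pydantic import BaseModel, field_validator

from .schema import ABDOMEN_CHEST

_PROB_TOL = 1e-6


@dataclass(frozen=True)
class SlicePrediction:
    """Class-probability vector for one slice (ordered by the internal vocabulary)."""

    probabilities: np.ndarray
    image_uid: str = ""
    indeterminate: bool = False

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        object.__setattr__(self, "probabilities", p)
        if p.ndim != 1 or p.size == 0:
            raise ValueError("probabilities must be a nonempty vector")
        if (p < -_PROB_TOL).any() or abs(p.sum() - 1.0) > _PROB_TOL:
            raise ValueError("probabilities must be nonnegative and sum to 1")

    @property
    def argmax_index(self) -> int:
        return int(np.argmax(self.probabilities))

    @property
    def confidence(self) -> float:
        return float(self.probabilities.max())


@dataclass
class PredictionSequence:
    """Per-slice predictions of one series, ordered by slice position."""

    entries: list[tuple[float, SlicePrediction]]
    modality: str = "CT"
    class_names: tuple[str, ...] = ()
    series_uid: str = ""

    def __post_init__(self) -> None:
        self.entries.sort(key=lambda e: e[0])

    def labels(self) -> list[str]:
        return [self.class_names[p.argmax_index] for _, p in self.entries]

    def prob_matrix(self) -> np.ndarray:
        if not self.entries:
            return np.zeros((0, len(self.class_names)))
        return np.stack([p.probabilities for _, p in self.entries])

    def with_probs(self, probs: np.ndarray, indeterminate: Optional[list[bool]] = None) -> "PredictionSequence":
        flags = indeterminate or [p.indeterminate for _, p in self.entries]
        new_entries = [
            (z, SlicePrediction(probabilities=row, image_uid=p.image_uid, indeterminate=flag))
            for (z, p), row, flag in zip(self.entries, probs, flags)
        ]
        return PredictionSequence(
            entries=new_entries, modality=self.modality,
            class_names=self.class_names, series_uid=self.series_uid,
        )

    def __len__(self) -> int:
        return len(self.entries)


class PostprocessConfig(BaseModel):
    breast_fraction_threshold: float = 0.5
    smoothing_window: int = 3
    confidence_threshold: float = 0.5
    outlier_max_iter: int = 100

    @field_validator("breast_fraction_threshold", "confidence_threshold")
    @classmethod
    def _unit(cls, v):
        if not 0 <= v <= 1:
            raise ValueError("threshold must be in [0, 1]")
        return v

    @field_validator("smoothing_window")
    @classmethod
    def _odd(cls, v):
        if v < 1 or v % 2 == 0:
            raise ValueError("smoothing window must be odd and >= 1")
        return v


def merge_abdomen_chest(seq: PredictionSequence) -> PredictionSequence:
    """Resolve the transitional class to abdomen or chest, series-wide.

    The target is whichever of abdomen/chest has more argmax slices in the
    series; a tie, or the absence of both, resolves to abdomen.  Every slice's
    abdomen-chest probability mass is reassigned to the target, so no
    downstream stage can re-emit the internal class.
    """
    if ABDOMEN_CHEST not in seq.class_names or not seq.entries:
        return seq
    names = seq.class_names
    ac = names.index(ABDOMEN_CHEST)
    labels = seq.labels()
    n_chest = labels.count("chest")
    n_abd = labels.count("abdomen")
    target = names.index("chest") if n_chest > n_abd else names.index("abdomen")
    probs = seq.prob_matrix()
    probs[:, target] += probs[:, ac]
    probs[:, ac] = 0.0
    return seq.with_probs(probs)


def breast_series_rule(seq: PredictionSequence, cfg: Optional[PostprocessConfig] = None) -> PredictionSequence:
    """Classify the entire series as breast when ≥ 50% of slices are (MRI only)."""
    cfg = cfg or PostprocessConfig()
    if seq.modality != "MRI" or "breast" not in seq.class_names or not seq.entries:
        return seq
    labels = seq.labels()
    fraction = labels.count("breast") / len(labels)
    if fraction < cfg.breast_fraction_threshold:
        return seq
    b = seq.class_names.index("breast")
    probs = np.zeros_like(seq.prob_matrix())
    probs[:, b] = 1.0
    return seq.with_probs(probs)


def remove_outliers(seq: PredictionSequence, max_iter: int = 100) -> PredictionSequence:
    """Replace isolated interior labels whose two flanking labels agree.

    The outlier slice's probability vector becomes the mean of its flanking
    vectors (argmax-preserving since the flanks share an argmax); endpoints are
    untouched; the pass repeats to a fixed point with an iteration cap.
    """
    if len(seq) < 3:
        return seq
    probs = seq.prob_matrix()
    for _ in range(max_iter):
        labels = probs.argmax(axis=1)
        changed = False
        for i in range(1, len(labels) - 1):
            if labels[i - 1] == labels[i + 1] != labels[i]:
                probs[i] = (probs[i - 1] + probs[i + 1]) / 2.0
                labels = probs.argmax(axis=1)
                changed = True
        if not changed:
            break
    return seq.with_probs(probs)


def smooth(seq: PredictionSequence, cfg: Optional[PostprocessConfig] = None) -> PredictionSequence:
    """Centred moving average of the per-class probability sequences.

    Edge windows are truncated; rows are renormalized and the argmax re-taken.
    A constant sequence is a fixed point.
    """
    cfg = cfg or PostprocessConfig()
    if len(seq) <= 1:
        return seq
    probs = seq.prob_matrix()
    half = cfg.smoothing_window // 2
    out = np.empty_like(probs)
    n = len(probs)
    for i in range(n):
        window = probs[max(0, i - half) : min(n, i + half + 1)]
        out[i] = window.mean(axis=0)
    out /= out.sum(axis=1, keepdims=True)
    return seq.with_probs(out)


def apply_threshold(seq: PredictionSequence, cfg: Optional[PostprocessConfig] = None) -> PredictionSequence:
    """Mark slices with confidence below the threshold as indeterminate.

    The boundary is inclusive: confidence exactly at the threshold is kept.
    Indeterminate slices are excluded from confusion-matrix accumulation.
    """
    cfg = cfg or PostprocessConfig()
    flags = [p.confidence < cfg.confidence_threshold for _, p in seq.entries]
    return seq.with_probs(seq.prob_matrix(), indeterminate=flags)


def postprocess_series(seq: PredictionSequence, cfg: Optional[PostprocessConfig] = None) -> PredictionSequence:
    """Full series-level chain: merge → breast rule → outliers → smoothing → threshold."""
    cfg = cfg or PostprocessConfig()
    seq = merge_abdomen_chest(seq)
    seq = breast_series_rule(seq, cfg)
    seq = remove_outliers(seq, cfg.outlier_max_iter)
    seq = smooth(seq, cfg)
    return apply_threshold(seq, cfg)
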