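"""Ground-truth machinery: thin 3D bounding boxes in patient coordinates.

An annotator delimits each body region once per exam with a thin axis-aligned
box in the patient coordinate system; the box then carries its label to every
series that shares the same frame of reference, so hundreds of slices are
labeled with a handful of clicks.  A slice is a candidate for a box's region
iff its center z position lies in the half-open interval ``[z_min, z_max)``
and the frames of reference match.  Half-open intervals prevent double
labeling at shared landmarks (the lesser trochanter bounds both pelvis and
thigh); where two boxes still claim one slice, a declared precedence list
resolves the tie.
"""

from __future__ import annotations

import csv
import json
import logging
import random
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

from .imaging import Study
from .schema import DEFAULT_PRECEDENCE

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BoundingBox3D:
    """Thin axis-aligned box in patient coordinates carrying one region label."""

    region: str
    x_min: float
    x_max: float
    y_min: float
    y_max: float
    z_min: float
    z_max: float
    frame_of_reference_uid: str

    def __post_init__(self) -> None:
        for lo, hi, ax in (
            (self.x_min, self.x_max, "x"),
            (self.y_min, self.y_max, "y"),
            (self.z_min, self.z_max, "z"),
        ):
            if not lo < hi:
                raise ValueError(f"box {self.region}: {ax}_min must be < {ax}_max")

    def contains_z(self, z: float) -> bool:
        return self.z_min <= z < self.z_max

    def to_dict(self) -> dict:
        return {
            "region": self.region,
            "x": [self.x_min, self.x_max],
            "y": [self.y_min, self.y_max],
            "z": [self.z_min, self.z_max],
            "frame_of_reference_uid": self.frame_of_reference_uid,
        }


def boxes_to_json(boxes: Sequence[BoundingBox3D], path: "str | Path") -> None:
    Path(path).write_text(json.dumps([b.to_dict() for b in boxes], indent=2))


def boxes_from_json(path: "str | Path") -> list[BoundingBox3D]:
    raw = json.loads(Path(path).read_text())
    return [
        BoundingBox3D(
            region=d["region"],
            x_min=d["x"][0], x_max=d["x"][1],
            y_min=d["y"][0], y_max=d["y"][1],
            z_min=d["z"][0], z_max=d["z"][1],
            frame_of_reference_uid=d["frame_of_reference_uid"],
        )
        for d in raw
    ]


def propagate(boxes: Sequence[BoundingBox3D], study: Study) -> dict[str, set[str]]:
    """Carry box labels to every in-frame slice; returns per-image candidate sets.

    Boxes are frame-local: a box only labels slices whose series share its
    frame of reference; slices of other frames receive nothing from it.  A box
    whose frame matches no series is ignored with a warning.
    """
    frames = {s.frame_of_reference_uid for s in study.series if len(s)}
    candidates: dict[str, set[str]] = {
        im.image_uid: set() for s in study.series for im in s.images
    }
    for box in boxes:
        if box.frame_of_reference_uid not in frames:
            logger.warning(
                "box %s: frame %s not present in study %s; ignored",
                box.region, box.frame_of_reference_uid, study.study_uid,
            )
            continue
        for series in study.series:
            if series.frame_of_reference_uid != box.frame_of_reference_uid:
                continue
            for im in series.images:
                if box.contains_z(im.z_position):
                    candidates[im.image_uid].add(box.region)
    return candidates


def resolve_labels(
    candidates: Mapping[str, set[str]],
    precedence: Sequence[str] = DEFAULT_PRECEDENCE,
) -> dict[str, Optional[str]]:
    """Resolve candidate sets to one label per image (or None when unlabeled).

    Singletons pass through; multi-candidate slices take the earliest region in
    the precedence list; empty sets map to None and are excluded from training
    and evaluation downstream.
    """
    rank = {name: i for i, name in enumerate(precedence)}
    missing = {r for s in candidates.values() for r in s} - set(rank)
    if missing:
        raise ValueError(f"precedence list does not cover regions: {sorted(missing)}")
    out: dict[str, Optional[str]] = {}
    for uid, cands in candidates.items():
        out[uid] = min(cands, key=rank.__getitem__) if cands else None
    return out


@dataclass(frozen=True)
class AuditReport:
    n_reviewed: int
    n_discrepant: int
    error_rate: float  # percent, rounded to one decimal
    discrepant_ids: tuple[str, ...]


def audit_labels(
    truth_a: Mapping[str, str],
    truth_b: Mapping[str, str],
    sample_fraction: float = 1.0,
    seed: int = 0,
) -> AuditReport:
    """Compare two independent labelings on a random study subset.

    Emulates the ground-truth quality review: a second reader re-labels a
    random fraction of studies and the discrepancy rate is reported as a
    percentage rounded to one decimal.
    """
    if not 0 < sample_fraction <= 1:
        raise ValueError("sample_fraction must be in (0, 1]")
    common = sorted(set(truth_a) & set(truth_b))
    n = max(1, round(sample_fraction * len(common))) if common else 0
    if n == 0:
        raise ValueError("empty audit sample: no studies common to both labelings")
    sampled = common if n >= len(common) else random.Random(seed).sample(common, n)
    discrepant = tuple(sid for sid in sampled if truth_a[sid] != truth_b[sid])
    rate = round(100.0 * len(discrepant) / len(sampled), 1)
    return AuditReport(len(sampled), len(discrepant), rate, discrepant)


def truth_to_csv(truth: Mapping[str, Optional[str]], path: "str | Path") -> None:
    """Export per-image truth as CSV (image uid, region); unlabeled rows blank."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["image_uid", "region"])
        for uid in sorted(truth):
            writer.writerow([uid, truth[uid] or ""])
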