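"""Patient-stratified partitioning and the survey sample-size model.

One patient must never appear in more than one partition (slices of the same
patient are correlated, so leakage inflates validation scores).  The split is
therefore performed on patient ids, per body region, with a seeded shuffle and
a 75/25 train/validation split by default; a patient imaged in several regions
is assigned once, by the first region listed for them.

The test-set size comes from a survey sampling model: to certify accuracy p
with a (1−α) confidence interval of relative half-width r one needs

    n_independent = ⌈ z² · (1 − p) / (r² · p) ⌉

independent samples (z the standard-normal quantile).  Consecutive slices are
not independent, so the count is multiplied by a ``design_effect`` — the
number of images per effectively independent sample, exposed as an explicit
parameter rather than a hard-coded constant.
"""

from __future__ import annotations

import csv
import math
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from pydantic import BaseModel, field_validator
from scipy import stats


@dataclass
class PartitionPlan:
    """Disjoint patient-id sets; union equals the cohort."""

    train: set[str]
    validation: set[str]
    test: set[str] = field(default_factory=set)
    split_fraction: float = 0.75

    def __post_init__(self) -> None:
        if self.train & self.validation or self.train & self.test or self.validation & self.test:
            raise ValueError("partitions must be pairwise disjoint")

    def partition_of(self, patient_id: str) -> str:
        if patient_id in self.train:
            return "train"
        if patient_id in self.validation:
            return "validation"
        if patient_id in self.test:
            return "test"
        raise KeyError(patient_id)

    def write_csv(self, path: "str | Path") -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["patient_id", "partition"])
            for name, ids in (("train", self.train), ("validation", self.validation), ("test", self.test)):
                for pid in sorted(ids):
                    writer.writerow([pid, name])


def split_patients(
    cohort: Sequence[tuple[str, str]],
    fraction: float = 0.75,
    seed: int = 0,
) -> PartitionPlan:
    """Seeded per-region 75/25 patient split with no patient in two partitions.

    ``cohort`` lists (patient_id, region) pairs; a patient appearing under
    several regions is stratified by their first-listed region, and all their
    studies land in the same partition.  Within each region the patient list is
    shuffled and split at ⌊fraction·n⌋.
    """
    if not cohort:
        raise ValueError("cohort is empty")
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    first_region: dict[str, str] = {}
    for pid, region in cohort:
        first_region.setdefault(pid, region)
    by_region: dict[str, list[str]] = {}
    for pid, region in first_region.items():
        by_region.setdefault(region, []).append(pid)
    rng = random.Random(seed)
    train: set[str] = set()
    validation: set[str] = set()
    for region in sorted(by_region):
        patients = sorted(by_region[region])
        rng.shuffle(patients)
        cut = math.floor(fraction * len(patients))
        train.update(patients[:cut])
        validation.update(patients[cut:])
    return PartitionPlan(train=train, validation=validation, split_fraction=fraction)


class SampleSizeSpec(BaseModel):
    """Survey-model inputs: target accuracy, CI level, relative error, design effect."""

    expected_accuracy: float = 0.90
    ci_level: float = 0.95
    relative_error: float = 0.10
    design_effect: float = 1.0

    @field_validator("expected_accuracy")
    @classmethod
    def _p(cls, v):
        if not 0 < v < 1:
            raise ValueError("expected_accuracy must be in (0, 1)")
        return v

    @field_validator("relative_error")
    @classmethod
    def _r(cls, v):
        if v <= 0:
            raise ValueError("relative_error must be positive")
        return v

    @field_validator("design_effect")
    @classmethod
    def _deff(cls, v):
        if v < 1:
            raise ValueError("design_effect must be >= 1")
        return v


def required_images(spec: SampleSizeSpec) -> int:
    """Images needed per body region in the test set.

    ``⌈z²(1−p)/(r²p)⌉`` independent samples scaled by the design effect.  With
    the defaults (p = 0.90, 95% CI, r = 0.10, design effect 1) this is 43.
    """
    z = stats.norm.ppf(1 - (1 - spec.ci_level) / 2)
    n_independent = math.ceil(
        z**2 * (1 - spec.expected_accuracy) / (spec.relative_error**2 * spec.expected_accuracy)
    )
    return math.ceil(n_independent * spec.design_effect)
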