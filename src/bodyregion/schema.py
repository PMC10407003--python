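"""Body-region vocabularies, anatomical landmark intervals, and modality configuration.

The classifier assigns one body region to every axial slice of a CT or MRI
series.  Seventeen regions are defined for CT and eighteen for MRI (breast is
imaged with dedicated MRI protocols only).  Each region is delimited along the
patient cranio-caudal axis by a pair of anatomical landmarks (e.g. the knee
spans the distal sixth of the femur down to the proximal sixth of the tibia).
An additional *internal* class, ``abdomen_chest``, captures slices at the
thoraco-abdominal junction; it is resolved to abdomen or chest by the
series-level rule engine and is never a final output label.

Conventions frozen here and relied on everywhere else:

* canonical snake_case region names, output classes ordered alphabetically,
  with ``abdomen_chest`` appended after the output classes so that output
  class indices form a prefix of the internal class indices;
* larger ``z`` is more cranial (DICOM patient coordinate convention);
* landmark intervals are half-open ``[top_z, bottom_z)`` on the z-axis once
  instantiated, with a configurable precedence list breaking ties where two
  regions share a landmark (e.g. lesser trochanter bounds both pelvis and
  thigh).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional


class Modality(str, Enum):
    CT = "CT"
    MRI = "MRI"


def _as_modality(modality: "Modality | str") -> Modality:
    if isinstance(modality, Modality):
        return modality
    try:
        return Modality(str(modality).upper().replace("MR", "MRI") if str(modality).upper() == "MR" else str(modality).upper())
    except ValueError:
        raise ValueError(
            f"unknown modality {modality!r}: expected one of {[m.value for m in Modality]}"
        ) from None


#: Canonical region names, alphabetical.  Breast is MRI-only.
_ALL_OUTPUT_REGIONS: tuple[str, ...] = (
    "abdomen",
    "arm",
    "breast",
    "calf",
    "chest",
    "elbow",
    "foot",
    "forearm",
    "hand",
    "head",
    "knee",
    "neck",
    "pelvis_hip",
    "shoulder",
    "spine_cervical",
    "spine_lumbar",
    "spine_thoracic",
    "thigh",
)

#: Internal transitional class for the thoraco-abdominal junction.
ABDOMEN_CHEST = "abdomen_chest"

_MRI_ONLY: frozenset[str] = frozenset({"breast"})


@dataclass(frozen=True)
class BodyRegion:
    """One anatomical output class.

    ``modality_scope`` is the set of modalities in which the region is a valid
    output label; breast is scoped to MRI only.
    """

    name: str
    modality_scope: frozenset[Modality] = field(
        default_factory=lambda: frozenset({Modality.CT, Modality.MRI})
    )

    def __post_init__(self) -> None:
        if self.name == "breast" and self.modality_scope != frozenset({Modality.MRI}):
            raise ValueError("breast is an MRI-only region")

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name


def _make_region(name: str) -> BodyRegion:
    if name in _MRI_ONLY:
        return BodyRegion(name, frozenset({Modality.MRI}))
    return BodyRegion(name)


@dataclass(frozen=True)
class LandmarkInterval:
    """Cranio-caudal extent of one region between two named anatomical landmarks.

    ``top_z``/``bottom_z`` are unset for the generic table and filled in per
    patient when ground truth is instantiated; cranial positions have larger z,
    so ``top_z > bottom_z``.  Membership is half-open: a slice belongs to the
    interval iff ``bottom_z < z <= top_z`` is *not* used — see
    :mod:`bodyregion.annotation`, which treats boxes as ``[z_min, z_max)`` on
    raw coordinates; the two conventions are consistent because the table is a
    naming layer only.
    """

    region: str
    top_landmark: str
    bottom_landmark: str
    top_z: Optional[float] = None
    bottom_z: Optional[float] = None

    def __post_init__(self) -> None:
        if self.top_z is not None and self.bottom_z is not None:
            if not self.top_z > self.bottom_z:
                raise ValueError(
                    f"{self.region}: top_z ({self.top_z}) must exceed bottom_z ({self.bottom_z})"
                )


_LANDMARKS: tuple[tuple[str, str, str], ...] = (
    ("abdomen", "Diaphragm/lung base", "Bifurcation of the aorta"),
    ("breast", "Skin surface of upper breast at chest wall", "Skin surface of lower breast at chest wall"),
    ("calf", "Proximal 6th of tibia", "Distal third of calf"),
    ("chest", "Lung apex", "Lung base"),
    ("elbow", "Distal 6th of humerus", "Proximal 6th of radius"),
    ("foot", "Distal third of calf", "Bottom of the foot"),
    ("forearm", "Proximal 6th of radius", "Distal 6th of radius"),
    ("hand", "Distal 6th of radius", "Tip of finger"),
    ("head", "Top of head", "Bottom of skull base (foramen magnum)"),
    ("arm", "Proximal 6th of humerus", "Distal 6th of humerus"),
    ("knee", "Distal 6th of femur", "Proximal 6th of tibia"),
    ("neck", "Skull base (foramen magnum)", "Lung apex"),
    ("pelvis_hip", "Aortic bifurcation", "Lesser trochanter (hip), inferior extent of pubis symphysis (pelvis)"),
    ("shoulder", "Top of acromioclavicular (AC) joint", "Proximal 6th of humerus"),
    ("spine_cervical", "Tip of odontoid", "Bottom of T1"),
    ("spine_thoracic", "Top of T1", "Bottom of T12"),
    ("spine_lumbar", "T11", "Mid sacrum (S2, S3)"),
    ("thigh", "Lesser trochanter", "Distal 6th of femur"),
)


def landmark_table() -> list[LandmarkInterval]:
    """Return the 18 uninstantiated landmark intervals, one per output region."""
    return [LandmarkInterval(r, top, bottom) for r, top, bottom in _LANDMARKS]


@dataclass(frozen=True)
class RegionVocabulary:
    """Fixed, ordered class vocabulary for one modality.

    ``output_classes`` are the final report labels (17 CT / 18 MRI, alphabetical);
    ``internal_classes`` append the transitional ``abdomen_chest`` class used by
    the slice classifier before the rule engine resolves it.  The position of a
    name in ``internal_classes`` is the classifier output index.
    """

    modality: Modality
    output_classes: tuple[BodyRegion, ...]

    @property
    def internal_classes(self) -> tuple[str, ...]:
        return self.output_names + (ABDOMEN_CHEST,)

    @property
    def output_names(self) -> tuple[str, ...]:
        return tuple(r.name for r in self.output_classes)

    def index_of(self, name: str) -> int:
        """Classifier output index of an internal class name."""
        try:
            return self.internal_classes.index(name)
        except ValueError:
            raise KeyError(f"{name!r} not in {self.modality.value} vocabulary") from None

    def __contains__(self, name: object) -> bool:
        return name in self.internal_classes

    def __len__(self) -> int:
        return len(self.output_classes)

    def to_json(self) -> str:
        """Serialize as JSON (name, index, modality scope) for checkpoints/reports."""
        payload = [
            {
                "name": name,
                "index": i,
                "modality_scope": sorted(m.value for m in _make_region(name).modality_scope)
                if name != ABDOMEN_CHEST
                else ["internal"],
            }
            for i, name in enumerate(self.internal_classes)
        ]
        return json.dumps({"modality": self.modality.value, "classes": payload}, indent=2)


def build_vocabulary(modality: "Modality | str") -> RegionVocabulary:
    """Build the fixed region vocabulary for a modality.

    CT has 17 output classes, MRI 18 (adds breast); ordering is alphabetical
    and stable across calls.
    """
    mod = _as_modality(modality)
    names = [n for n in _ALL_OUTPUT_REGIONS if mod == Modality.MRI or n not in _MRI_ONLY]
    return RegionVocabulary(modality=mod, output_classes=tuple(_make_region(n) for n in names))


#: Default precedence used when a slice is claimed by two instantiated intervals
#: (shared landmarks: spine vs body cavity, pelvis vs thigh).  Spine classes win,
#: then remaining regions in vocabulary order.  A declared convention, configurable
#: wherever it is consumed.
DEFAULT_PRECEDENCE: tuple[str, ...] = (
    "spine_cervical",
    "spine_thoracic",
    "spine_lumbar",
) + tuple(n for n in _ALL_OUTPUT_REGIONS if not n.startswith("spine_"))
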