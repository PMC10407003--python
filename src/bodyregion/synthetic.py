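"""Seedable phantom studies for desk-scale exercise of the whole pipeline.

Each body region is rendered as a distinctive, deliberately simple geometric
texture (a filled blob whose vertical position, size and brightness are unique
to the region, plus a ring for alternating classes).  Anatomical realism is a
non-goal: the generator's contract is *distinguishable, geometry-consistent*
classes with full DICOM-style metadata, so that training, inference, rule
post-processing and evaluation can all run end-to-end without clinical data.

Slices are stacked cranio-caudal (larger z = more cranial) with configurable
spacing, thickness, noise and obliquity.  Region boundaries are blended
linearly over a configurable transition zone to emulate the ambiguous
junction slices that dominate real misclassifications; within the
chest/abdomen transition the *internal* training label is the transitional
``abdomen_chest`` class, while the final ground truth (from the bounding
boxes) remains chest or abdomen.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from pydantic import BaseModel, Field, field_validator

from .annotation import BoundingBox3D, propagate, resolve_labels
from .imaging import ImageRecord, Series, Study
from .schema import ABDOMEN_CHEST, Modality, build_vocabulary

#: Full-body texture index: position in the MRI output vocabulary, so a given
#: region looks identical under CT and MRI.
_TEXTURE_ORDER = build_vocabulary(Modality.MRI).output_names


class PhantomSpec(BaseModel):
    """Recipe for one phantom study.

    ``regions_present`` lists (region, extent_mm) pairs ordered cranial →
    caudal; the study spans their summed extent with one axial slice every
    ``slice_spacing_mm``.
    """

    modality: Modality = Modality.MRI
    regions_present: list[tuple[str, float]]
    slice_spacing_mm: float = 5.0
    slice_thickness_mm: float = 5.0
    image_size: int = 96
    noise_sd: float = 8.0
    intensity_scale: float = 400.0
    obliquity_deg: float = 0.0
    transition_zone_mm: float = 10.0
    n_series: int = 1
    seed: int = 0
    patient_id: str = "P0000"
    study_uid: str = "S0000"
    manufacturer_dist: dict[str, float] = Field(
        default_factory=lambda: {"Siemens": 0.6, "GE": 0.2, "Philips": 0.15, "Toshiba": 0.05}
    )
    contrast_prob: float = 0.2
    sequence_dist: dict[str, float] = Field(
        default_factory=lambda: {"image_weighting": 0.7, "gradient_echo": 0.2, "inversion_recovery": 0.1}
    )

    @field_validator("regions_present")
    @classmethod
    def _positive_extents(cls, v):
        if not v:
            raise ValueError("regions_present must be nonempty")
        for region, extent in v:
            if extent <= 0:
                raise ValueError(f"extent for {region} must be positive")
        return v

    @field_validator("slice_spacing_mm", "slice_thickness_mm", "intensity_scale")
    @classmethod
    def _positive(cls, v):
        if v <= 0:
            raise ValueError("must be positive")
        return v


@dataclass
class PhantomStudy:
    """A generated study plus its ground truth.

    ``truth`` maps image uid → final region label (box-derived, never
    ``abdomen_chest``); ``internal_truth`` maps image uid → the training label,
    which is ``abdomen_chest`` for slices inside the chest/abdomen transition
    zone and equals ``truth`` elsewhere.
    """

    study: Study
    truth: dict[str, str]
    internal_truth: dict[str, str]
    boxes: list[BoundingBox3D] = field(default_factory=list)


def region_texture(region: str, size: int) -> np.ndarray:
    """Deterministic base texture for a region, values in [0, 1].

    One filled disc whose row position, radius and brightness encode the
    region index, plus a concentric ring for alternating indices; the distinct
    row position makes classes separable even on row-mean intensity profiles.
    """
    try:
        i = _TEXTURE_ORDER.index(region)
    except ValueError:
        raise ValueError(f"unknown region {region!r}") from None
    n = len(_TEXTURE_ORDER)
    yy, xx = np.meshgrid(
        np.linspace(-1, 1, size), np.linspace(-1, 1, size), indexing="ij"
    )
    cy = -0.75 + 1.5 * i / (n - 1)
    cx = -0.45 + 0.45 * (i % 3)
    radius = 0.16 + 0.02 * (i % 4)
    level = 0.4 + 0.6 * (i + 1) / n
    img = np.zeros((size, size))
    img[(yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2] = level
    if i % 2 == 1:
        rad = np.sqrt(yy**2 + xx**2)
        img[(rad >= 0.55) & (rad <= 0.65)] = np.maximum(
            img[(rad >= 0.55) & (rad <= 0.65)], 0.3
        )
    return img


def _sample_categorical(rng: np.random.Generator, dist: dict[str, float]) -> str:
    keys = sorted(dist)
    probs = np.array([dist[k] for k in keys], dtype=float)
    probs = probs / probs.sum()
    return keys[int(rng.choice(len(keys), p=probs))]


def generate_study(spec: PhantomSpec) -> PhantomStudy:
    """Render one phantom study from a spec; fully deterministic under its seed."""
    vocab = build_vocabulary(spec.modality)
    for region, _ in spec.regions_present:
        if region not in vocab.output_names:
            raise ValueError(
                f"region {region!r} is not in the {spec.modality.value} vocabulary"
            )

    rng = np.random.default_rng(spec.seed)
    total_extent = sum(extent for _, extent in spec.regions_present)
    frame_uid = f"FOR-{spec.study_uid}"

    # Region intervals on z, cranial (top, z=total_extent) to caudal (z=0).
    intervals: list[tuple[str, float, float]] = []  # (region, z_min, z_max)
    z_top = total_extent
    for region, extent in spec.regions_present:
        intervals.append((region, z_top - extent, z_top))
        z_top -= extent
    boxes = [
        BoundingBox3D(
            region=r,
            x_min=-250.0, x_max=250.0, y_min=-250.0, y_max=250.0,
            z_min=z_lo, z_max=z_hi,
            frame_of_reference_uid=frame_uid,
        )
        for r, z_lo, z_hi in intervals
    ]
    textures = {r: region_texture(r, spec.image_size) for r, _ in spec.regions_present}

    n_slices = int(total_extent // spec.slice_spacing_mm)
    z_positions = total_extent - spec.slice_spacing_mm * (np.arange(n_slices) + 0.5)

    series_list = []
    internal_truth: dict[str, str] = {}
    for s_idx in range(spec.n_series):
        series_uid = f"{spec.study_uid}-SE{s_idx}"
        images = []
        for k, z in enumerate(z_positions):
            base, internal = _slice_texture(z, intervals, textures, spec)
            pixels = base * spec.intensity_scale
            if spec.noise_sd > 0:
                pixels = pixels + rng.normal(0.0, spec.noise_sd, pixels.shape)
            uid = f"{series_uid}-IM{k:04d}"
            images.append(
                ImageRecord(
                    pixels=pixels,
                    z_position=float(z),
                    slice_thickness=spec.slice_thickness_mm,
                    obliquity_deg=spec.obliquity_deg,
                    bits_stored=16,
                    n_channels=1,
                    image_uid=uid,
                    series_uid=series_uid,
                    study_uid=spec.study_uid,
                    patient_id=spec.patient_id,
                    frame_of_reference_uid=frame_uid,
                )
            )
            internal_truth[uid] = internal
        series_list.append(
            Series(
                images=images,
                series_uid=series_uid,
                series_type="axial_primary",
                modality=spec.modality.value,
                manufacturer=_sample_categorical(rng, spec.manufacturer_dist),
                contrast=bool(rng.random() < spec.contrast_prob),
                sequence_family=_sample_categorical(rng, spec.sequence_dist)
                if spec.modality == Modality.MRI
                else ("bone" if rng.random() < 0.3 else "soft_tissue"),
            )
        )

    study = Study(series=series_list, study_uid=spec.study_uid, patient_id=spec.patient_id)
    resolved = resolve_labels(propagate(boxes, study))
    truth = {uid: r for uid, r in resolved.items() if r is not None}
    return PhantomStudy(study=study, truth=truth, internal_truth=internal_truth, boxes=boxes)


def _slice_texture(
    z: float,
    intervals: Sequence[tuple[str, float, float]],
    textures: dict[str, np.ndarray],
    spec: PhantomSpec,
) -> tuple[np.ndarray, str]:
    """Texture and internal training label for the slice at position z.

    Within ``transition_zone_mm`` of an internal boundary the two adjacent
    textures are blended linearly; a blended chest/abdomen slice is labeled
    with the transitional class.
    """
    region = None
    for r, z_lo, z_hi in intervals:
        if z_lo <= z < z_hi:
            region = r
            break
    if region is None:  # numeric edge: clamp to nearest interval
        region = intervals[0][0] if z >= intervals[0][2] else intervals[-1][0]
    base = textures[region].copy()
    internal = region
    half = spec.transition_zone_mm / 2.0
    if half > 0:
        for (r_up, lo_up, _), (r_dn, _, hi_dn) in zip(intervals, intervals[1:]):
            boundary = lo_up  # == hi_dn: shared landmark between adjacent regions
            if abs(z - boundary) <= half:
                w_dn = (boundary + half - z) / (2 * half)  # 0 at top edge, 1 at bottom
                base = (1 - w_dn) * textures[r_up] + w_dn * textures[r_dn]
                if {r_up, r_dn} == {"chest", "abdomen"}:
                    internal = ABDOMEN_CHEST
                break
    return base, internal


def default_compositions(modality: "Modality | str") -> list[list[tuple[str, float]]]:
    """Study compositions (region, extent_mm) emulating common scan coverages.

    Single-region exams for every class in the modality vocabulary, plus
    multi-region trunk exams that exercise the chest/abdomen junction and
    spine overlaps.
    """
    vocab = build_vocabulary(modality)
    single = [[(r, 150.0)] for r in vocab.output_names]
    multi = [
        [("chest", 150.0), ("abdomen", 150.0)],
        [("neck", 100.0), ("chest", 150.0)],
        [("abdomen", 120.0), ("pelvis_hip", 120.0)],
        [("chest", 120.0), ("abdomen", 120.0), ("pelvis_hip", 120.0)],
    ]
    return single + multi


def generate_cohort(
    n_patients: int,
    spec_distribution: Optional[list[list[tuple[str, float]]]] = None,
    seed: int = 0,
    modality: "Modality | str" = Modality.MRI,
    balanced: bool = False,
    **spec_overrides,
) -> list[PhantomStudy]:
    """Generate one study per patient with unique patient ids.

    Compositions come from ``spec_distribution`` (default:
    :func:`default_compositions`); they are sampled uniformly with the seeded
    generator, or cycled deterministically when ``balanced`` is set so every
    composition appears ``⌈n/len⌉`` or ``⌊n/len⌋`` times.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    comps = spec_distribution or default_compositions(modality)
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_patients):
        comp = comps[i % len(comps)] if balanced else comps[int(rng.integers(len(comps)))]
        spec = PhantomSpec(
            modality=Modality(modality) if not isinstance(modality, Modality) else modality,
            regions_present=comp,
            seed=int(rng.integers(2**31 - 1)),
            patient_id=f"P{i:04d}",
            study_uid=f"S{i:04d}",
            **spec_overrides,
        )
        out.append(generate_study(spec))
    return out
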