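"""Patient → study → series → image data model, DICOM reading, and exclusion filters.

The unit of classification is a 2D axial slice; slices are grouped into series
(one acquisition), series into studies (one exam), and studies belong to a
patient.  Only primary axial acquisitions are classified: scouts, reformats and
other derived series are dropped, and individual images are dropped when they
are too oblique (> 45° from the axial plane), stored at 8 bits or lower, not
grayscale, nearly empty (< 1000 pixels) or missing pixel data.  Every removal
is recorded with a single reason in an :class:`ExclusionLog` so that
``retained + excluded == input``.
"""

from __future__ import annotations

import csv
import logging
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
from pydantic import BaseModel

logger = logging.getLogger(__name__)

SERIES_TYPES = ("axial_primary", "scout", "reformat", "secondary", "other")


@dataclass
class ImageRecord:
    """One 2D grayscale slice with its geometry and acquisition metadata."""

    pixels: Optional[np.ndarray]  # 2D array; None when the file had no pixel data
    z_position: float  # mm, slice-center position on the patient z axis
    slice_thickness: float  # mm
    obliquity_deg: float  # angle between slice normal and patient z axis
    bits_stored: int
    n_channels: int
    image_uid: str
    series_uid: str
    study_uid: str
    patient_id: str
    frame_of_reference_uid: str

    @property
    def pixel_count(self) -> int:
        return 0 if self.pixels is None else int(np.prod(self.pixels.shape[:2]))


@dataclass
class Series:
    """A stack of slices from one acquisition, sorted caudal → cranial by z."""

    images: list[ImageRecord]
    series_uid: str
    series_type: str = "axial_primary"
    modality: str = "CT"
    manufacturer: str = "unknown"
    contrast: bool = False
    sequence_family: str = ""  # CT kernel or MRI sequence family
    institution_type: str = ""
    patient_age_band: str = ""
    patient_sex: str = ""

    def __post_init__(self) -> None:
        if self.series_type not in SERIES_TYPES:
            raise ValueError(f"unknown series_type {self.series_type!r}")
        self.images.sort(key=lambda im: im.z_position)

    @property
    def frame_of_reference_uid(self) -> str:
        return self.images[0].frame_of_reference_uid if self.images else ""

    def __len__(self) -> int:
        return len(self.images)


@dataclass
class Study:
    """One exam: all series acquired in one visit, sharing a study UID."""

    series: list[Series]
    study_uid: str
    patient_id: str

    @property
    def n_images(self) -> int:
        return sum(len(s) for s in self.series)

    def __iter__(self):
        return iter(self.series)


@dataclass
class ExclusionLog:
    """Per-item removal reasons; one entry per excluded image or series."""

    entries: list[tuple[str, str]] = field(default_factory=list)  # (uid, reason)

    def add(self, uid: str, reason: str) -> None:
        self.entries.append((uid, reason))

    def reasons(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for _, reason in self.entries:
            out[reason] = out.get(reason, 0) + 1
        return out

    def write_csv(self, path: "str | Path") -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["uid", "reason"])
            writer.writerows(self.entries)

    def __len__(self) -> int:
        return len(self.entries)


class FilterConfig(BaseModel):
    """Image-level inclusion thresholds.

    Defaults implement the published criteria: axial obliquity up to 45°
    (inclusive), more than 8 bits stored, single-channel grayscale, and at
    least 1000 pixels of data.
    """

    max_obliquity_deg: float = 45.0
    min_bits_stored_exclusive: int = 8
    min_pixel_count: int = 1000
    require_single_channel: bool = True


#: SeriesDescription / ImageType keywords → series type, checked in order.
SERIES_TYPE_KEYWORDS: tuple[tuple[str, str], ...] = (
    ("scout", "scout"),
    ("localizer", "scout"),
    ("topogram", "scout"),
    ("calibration", "scout"),
    ("reformat", "reformat"),
    ("mpr", "reformat"),
    ("coronal", "reformat"),
    ("sagittal", "reformat"),
    ("secondary", "secondary"),
    ("derived", "secondary"),
    ("screen save", "secondary"),
)


def classify_series_type(description: str, image_type: Iterable[str] = ()) -> str:
    """Heuristic series-type detection from DICOM SeriesDescription/ImageType."""
    text = " ".join([description, *image_type]).lower()
    for keyword, stype in SERIES_TYPE_KEYWORDS:
        if keyword in text:
            return stype
    return "axial_primary"


def obliquity_from_orientation(image_orientation: Iterable[float]) -> float:
    """Angle (degrees) between the slice normal and the patient z axis.

    ``image_orientation`` is the 6-element DICOM ImageOrientationPatient
    (row direction cosines then column direction cosines).
    """
    v = np.asarray(list(image_orientation), dtype=float)
    if v.shape != (6,):
        raise ValueError("ImageOrientationPatient must have 6 components")
    normal = np.cross(v[:3], v[3:])
    norm = np.linalg.norm(normal)
    if norm == 0:
        return 90.0
    cosang = abs(normal[2]) / norm
    return math.degrees(math.acos(min(1.0, cosang)))


def filter_images(study: Study, rules: Optional[FilterConfig] = None) -> tuple[Study, ExclusionLog]:
    """Apply image-level inclusion criteria; never raises.

    Retained images satisfy: obliquity ≤ 45°, bits stored > 8, single channel,
    ≥ 1000 pixels, and pixel data present.  The first failing criterion is the
    recorded reason.
    """
    rules = rules or FilterConfig()
    log = ExclusionLog()
    new_series = []
    for s in study.series:
        kept = []
        for im in s.images:
            reason = _image_exclusion_reason(im, rules)
            if reason is None:
                kept.append(im)
            else:
                log.add(im.image_uid, reason)
        new_series.append(replace(s, images=kept))
    return Study(series=new_series, study_uid=study.study_uid, patient_id=study.patient_id), log


def _image_exclusion_reason(im: ImageRecord, rules: FilterConfig) -> Optional[str]:
    if im.pixels is None:
        return "no_pixel_data"
    if im.obliquity_deg > rules.max_obliquity_deg:
        return "obliquity"
    if im.bits_stored <= rules.min_bits_stored_exclusive:
        return "bit_depth"
    if rules.require_single_channel and im.n_channels != 1:
        return "multi_channel"
    if im.pixel_count < rules.min_pixel_count:
        return "pixel_count"
    return None


def filter_series(study: Study) -> tuple[Study, ExclusionLog]:
    """Keep only primary axial series; scouts, reformats, secondaries removed."""
    log = ExclusionLog()
    kept = []
    for s in study.series:
        if s.series_type == "axial_primary":
            kept.append(s)
        else:
            log.add(s.series_uid, f"series_type:{s.series_type}")
    if not kept:
        logger.warning("study %s: no primary axial series retained", study.study_uid)
    return Study(series=kept, study_uid=study.study_uid, patient_id=study.patient_id), log


# ---------------------------------------------------------------------------
# DICOM reading / fixture writing
# ---------------------------------------------------------------------------

def load_study(path: "str | Path") -> list[Study]:
    """Load all studies found in a directory of single-frame DICOM files.

    Files are grouped by (patient, study, series) identifiers and slices sorted
    by z position.  Files without pixel data are kept as flagged records (the
    image filter excludes them with a logged reason); unreadable files are
    logged and skipped.
    """
    import pydicom

    path = Path(path)
    files = sorted(p for p in path.rglob("*") if p.is_file())
    records: dict[tuple[str, str], dict[str, list[ImageRecord]]] = {}
    series_meta: dict[str, dict] = {}
    n_unreadable = 0
    # pydicom validates UI elements lazily on access; tolerate fixture
    # identifiers that are readable strings rather than registered UIDs
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="Invalid value for VR UI")
        for f in files:
            try:
                ds = pydicom.dcmread(f)
            except Exception:  # not a DICOM file or unsupported syntax
                n_unreadable += 1
                continue
            try:
                pixels = ds.pixel_array.astype(np.float64)
                if "RescaleSlope" in ds or "RescaleIntercept" in ds:
                    pixels = pixels * float(getattr(ds, "RescaleSlope", 1.0)) + float(
                        getattr(ds, "RescaleIntercept", 0.0)
                    )
            except Exception:
                pixels = None
            orientation = list(getattr(ds, "ImageOrientationPatient", [1, 0, 0, 0, 1, 0]))
            position = list(getattr(ds, "ImagePositionPatient", [0.0, 0.0, 0.0]))
            rec = ImageRecord(
                pixels=pixels,
                z_position=float(position[2]),
                slice_thickness=float(getattr(ds, "SliceThickness", 1.0)),
                obliquity_deg=obliquity_from_orientation(orientation),
                bits_stored=int(getattr(ds, "BitsStored", 16)),
                n_channels=int(getattr(ds, "SamplesPerPixel", 1)),
                image_uid=str(getattr(ds, "SOPInstanceUID", f.name)),
                series_uid=str(getattr(ds, "SeriesInstanceUID", "series")),
                study_uid=str(getattr(ds, "StudyInstanceUID", "study")),
                patient_id=str(getattr(ds, "PatientID", "patient")),
                frame_of_reference_uid=str(getattr(ds, "FrameOfReferenceUID", "frame")),
            )
            key = (rec.patient_id, rec.study_uid)
            records.setdefault(key, {}).setdefault(rec.series_uid, []).append(rec)
            series_meta.setdefault(
                rec.series_uid,
                {
                    "modality": str(getattr(ds, "Modality", "CT")),
                    "manufacturer": str(getattr(ds, "Manufacturer", "unknown")),
                    "series_type": classify_series_type(
                        str(getattr(ds, "SeriesDescription", "")),
                        [str(t) for t in getattr(ds, "ImageType", [])],
                    ),
                },
            )
    if n_unreadable:
        logger.warning("skipped %d unreadable files under %s", n_unreadable, path)
    studies = []
    for (patient_id, study_uid), by_series in sorted(records.items()):
        series = [
            Series(
                images=imgs,
                series_uid=suid,
                series_type=series_meta[suid]["series_type"],
                modality="MRI" if series_meta[suid]["modality"].upper().startswith("MR") else "CT",
                manufacturer=series_meta[suid]["manufacturer"],
            )
            for suid, imgs in sorted(by_series.items())
        ]
        studies.append(Study(series=series, study_uid=study_uid, patient_id=patient_id))
    return studies


def write_dicom_series(series: Series, out_dir: "str | Path", modality: Optional[str] = None) -> list[Path]:
    """Write a series as one secondary-capture-style DICOM file per slice.

    Minimal writer for fixtures and the `simulate` command: geometry tags
    (position, thickness, orientation), identifiers, and 16-bit pixel data.
    """
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, SecondaryCaptureImageStorage

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    with warnings.catch_warnings():
        # fixture identifiers are readable strings, not registered UIDs
        warnings.filterwarnings("ignore", message="Invalid value for VR UI")
        for i, im in enumerate(series.images):
            meta = FileMetaDataset()
            meta.MediaStorageSOPClassUID = SecondaryCaptureImageStorage
            meta.MediaStorageSOPInstanceUID = pydicom.uid.generate_uid()
            meta.TransferSyntaxUID = ExplicitVRLittleEndian
            ds = FileDataset(None, {}, file_meta=meta, preamble=b"\x00" * 128)
            ds.SOPClassUID = SecondaryCaptureImageStorage
            ds.SOPInstanceUID = im.image_uid
            ds.PatientID = im.patient_id
            ds.PatientName = im.patient_id
            ds.StudyInstanceUID = im.study_uid
            ds.SeriesInstanceUID = im.series_uid
            ds.FrameOfReferenceUID = im.frame_of_reference_uid
            ds.Modality = modality or series.modality
            ds.Manufacturer = series.manufacturer
            ds.SeriesDescription = series.series_type
            ds.ImagePositionPatient = [0.0, 0.0, float(im.z_position)]
            theta = math.radians(im.obliquity_deg)
            ds.ImageOrientationPatient = [1, 0, 0, 0, math.cos(theta), math.sin(theta)]
            ds.SliceThickness = float(im.slice_thickness)
            px = im.pixels if im.pixels is not None else np.zeros((2, 2))
            arr = np.clip(px, 0, 65535).astype(np.uint16)
            ds.Rows, ds.Columns = arr.shape
            ds.SamplesPerPixel = max(1, im.n_channels)
            ds.PhotometricInterpretation = "MONOCHROME2"
            ds.BitsAllocated = 16
            ds.BitsStored = im.bits_stored
            ds.HighBit = 15
            ds.PixelRepresentation = 0
            ds.PixelData = arr.tobytes()
            out = out_dir / f"{series.series_uid}_{i:04d}.dcm"
            ds.save_as(out, enforce_file_format=True)
            written.append(out)
    return written
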