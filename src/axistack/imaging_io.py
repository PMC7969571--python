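"""Slice-series I/O and the geometric conventions shared by the whole pipeline.

A study is an ordered stack of transaxial grayscale slices, each carrying its
own geometry metadata (in-plane pixel spacing, slice thickness, through-plane
position).  Two on-disk dialects are supported:

* ``sidecar`` — one 16-bit grayscale PNG per slice (plus an 8-bit PNG label
  map when labels exist) and a small JSON file with the geometry, tied
  together by a series-level ``series.json``.  Read/write; used for all
  synthetic data and round-trip tests.
* ``dicom`` — a directory of single-frame axial DICOM files.  Read only;
  the tags consumed are PixelSpacing, SliceThickness, ImagePositionPatient
  (z component) and Manufacturer.

Coordinate conventions (relied on by reconstruction and quantification):
pixel indices are 0-based; the world position of a voxel *center* is
``slice_position`` along z and ``(index + 0.5) * spacing`` in-plane.  Rows
run anterior→posterior, columns left→right, and ascending ``slice_position``
defines the z-axis (caudal→cranial).  Slices are always kept sorted by
ascending ``slice_position``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from enum import IntEnum
from pathlib import Path
from typing import Optional, Sequence

import imageio.v3 as iio
import numpy as np

REPORT_SCHEMA_VERSION = "1.0"

# Manufacturer categories. Real studies map their DICOM Manufacturer tag onto
# one of the two calibrated vendors; anything unrecognized falls back to
# UNCALIBRATED, for which calibration is the identity.
MANUFACTURER_A = "A"
MANUFACTURER_B = "B"
MANUFACTURER_UNCALIBRATED = "uncalibrated"
MANUFACTURERS = (MANUFACTURER_A, MANUFACTURER_B, MANUFACTURER_UNCALIBRATED)

_DICOM_MANUFACTURER_MAP = {
    "siemens": MANUFACTURER_A,
    "philips": MANUFACTURER_B,
}


class LabelClass(IntEnum):
    """The 9-way per-pixel vocabulary: 8 anatomical structures + background."""

    background = 0
    aorta = 1
    left_atrium = 2
    lv_wall = 3
    lv_cavity = 4
    pulmonary_artery = 5
    pleural_effusion = 6
    right_atrium = 7
    rv_cavity = 8


FOREGROUND_CLASSES = tuple(c for c in LabelClass if c != LabelClass.background)
N_CLASSES = len(LabelClass)


@dataclass(frozen=True)
class SliceGeometry:
    """Per-slice acquisition geometry, all lengths in millimetres."""

    pixel_spacing_row: float
    pixel_spacing_col: float
    slice_thickness: float
    slice_position: float
    rows: int
    cols: int

    def __post_init__(self) -> None:
        if self.pixel_spacing_row <= 0 or self.pixel_spacing_col <= 0:
            raise ValueError("pixel spacings must be strictly positive")
        if self.slice_thickness <= 0:
            raise ValueError("slice_thickness must be strictly positive")
        if self.rows < 1 or self.cols < 1:
            raise ValueError("rows and cols must be >= 1")


@dataclass
class SliceRecord:
    """One 2D grayscale slice, optionally with a per-pixel label map."""

    image: np.ndarray
    geometry: SliceGeometry
    labels: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image)
        if self.image.ndim != 2:
            raise ValueError("image must be 2D")
        if self.image.shape != (self.geometry.rows, self.geometry.cols):
            raise ValueError("image shape disagrees with geometry rows/cols")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape != self.image.shape:
                raise ValueError("labels must have the same shape as image")
            if self.labels.size and (
                self.labels.min() < 0 or self.labels.max() >= N_CLASSES
            ):
                raise ValueError("labels contain invalid class ids")


@dataclass
class SeriesRecord:
    """An ordered slice stack plus study-level metadata.

    ``bsa`` (m²) or ``height_cm``/``weight_kg`` are optional; the manufacturer
    must be present whenever calibration is applied downstream.
    """

    slices: list[SliceRecord] = field(default_factory=list)
    manufacturer: str = MANUFACTURER_UNCALIBRATED
    bsa: Optional[float] = None
    height_cm: Optional[float] = None
    weight_kg: Optional[float] = None

    def __post_init__(self) -> None:
        if self.manufacturer not in MANUFACTURERS:
            raise ValueError(f"unknown manufacturer category {self.manufacturer!r}")
        positions = [s.geometry.slice_position for s in self.slices]
        if len(set(positions)) != len(positions):
            raise ValueError("duplicate slice_position in series")
        self.slices = sorted(self.slices, key=lambda s: s.geometry.slice_position)

    @property
    def positions(self) -> np.ndarray:
        return np.array([s.geometry.slice_position for s in self.slices])


def _series_equal(a: SeriesRecord, b: SeriesRecord) -> bool:
    if len(a.slices) != len(b.slices):
        return False
    for sa, sb in zip(a.slices, b.slices):
        if sa.geometry != sb.geometry:
            return False
        if not np.array_equal(sa.image, sb.image):
            return False
        if (sa.labels is None) != (sb.labels is None):
            return False
        if sa.labels is not None and not np.array_equal(sa.labels, sb.labels):
            return False
    return (
        a.manufacturer == b.manufacturer
        and a.bsa == b.bsa
        and a.height_cm == b.height_cm
        and a.weight_kg == b.weight_kg
    )


SeriesRecord.__eq__ = lambda self, other: (  # type: ignore[assignment]
    isinstance(other, SeriesRecord) and _series_equal(self, other)
)


# ---------------------------------------------------------------------------
# sidecar dialect
# ---------------------------------------------------------------------------

def _geometry_to_json(g: SliceGeometry) -> dict:
    return {
        "pixel_spacing_row_mm": g.pixel_spacing_row,
        "pixel_spacing_col_mm": g.pixel_spacing_col,
        "slice_thickness_mm": g.slice_thickness,
        "slice_position_mm": g.slice_position,
        "rows": g.rows,
        "cols": g.cols,
    }


def _geometry_from_json(d: dict, where: str) -> SliceGeometry:
    required = [
        "pixel_spacing_row_mm",
        "pixel_spacing_col_mm",
        "slice_thickness_mm",
        "slice_position_mm",
        "rows",
        "cols",
    ]
    for key in required:
        if key not in d or d[key] is None:
            raise ValueError(f"missing geometry field {key!r} on {where}")
    return SliceGeometry(
        pixel_spacing_row=float(d["pixel_spacing_row_mm"]),
        pixel_spacing_col=float(d["pixel_spacing_col_mm"]),
        slice_thickness=float(d["slice_thickness_mm"]),
        slice_position=float(d["slice_position_mm"]),
        rows=int(d["rows"]),
        cols=int(d["cols"]),
    )


def write_series(series: SeriesRecord, path: str | Path, dialect: str = "sidecar") -> None:
    """Write a series to ``path``; only the sidecar dialect is writable.

    Guarantees bit-exact round-trip through :func:`read_series` for images
    (uint16), labels (uint8) and geometry.
    """
    if dialect != "sidecar":
        raise ValueError(f"write_series supports only the sidecar dialect, got {dialect!r}")
    if not series.slices:
        raise ValueError("refusing to write an empty series")
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "manufacturer": series.manufacturer,
        "bsa_m2": series.bsa,
        "height_cm": series.height_cm,
        "weight_kg": series.weight_kg,
        "slices": [],
    }
    for i, s in enumerate(series.slices):
        stem = f"slice_{i:04d}"
        img = np.asarray(s.image)
        if img.dtype != np.uint16:
            if not np.issubdtype(img.dtype, np.integer):
                raise ValueError("sidecar images must be integer-valued (uint16)")
            if img.min() < 0 or img.max() > np.iinfo(np.uint16).max:
                raise ValueError("image values out of uint16 range")
            img = img.astype(np.uint16)
        iio.imwrite(path / f"{stem}.png", img)
        entry = {"image": f"{stem}.png", "geometry": _geometry_to_json(s.geometry)}
        if s.labels is not None:
            iio.imwrite(path / f"{stem}_labels.png", s.labels.astype(np.uint8))
            entry["labels"] = f"{stem}_labels.png"
        manifest["slices"].append(entry)
    (path / "series.json").write_text(json.dumps(manifest, indent=1))


def _read_sidecar(path: Path) -> SeriesRecord:
    manifest_path = path / "series.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no series.json in {path}")
    manifest = json.loads(manifest_path.read_text())
    slices = []
    for i, entry in enumerate(manifest["slices"]):
        geometry = _geometry_from_json(entry.get("geometry", {}), f"slice index {i}")
        image = np.asarray(iio.imread(path / entry["image"]))
        labels = None
        if entry.get("labels"):
            labels = np.asarray(iio.imread(path / entry["labels"])).astype(np.uint8)
        slices.append(SliceRecord(image=image, geometry=geometry, labels=labels))
    return SeriesRecord(
        slices=slices,
        manufacturer=manifest.get("manufacturer", MANUFACTURER_UNCALIBRATED),
        bsa=manifest.get("bsa_m2"),
        height_cm=manifest.get("height_cm"),
        weight_kg=manifest.get("weight_kg"),
    )


# ---------------------------------------------------------------------------
# DICOM dialect (read only)
# ---------------------------------------------------------------------------

def map_manufacturer(tag: Optional[str]) -> str:
    """Map a free-text DICOM Manufacturer tag onto a calibration category."""
    if not tag:
        return MANUFACTURER_UNCALIBRATED
    lowered = tag.strip().lower()
    for key, cat in _DICOM_MANUFACTURER_MAP.items():
        if key in lowered:
            return cat
    return MANUFACTURER_UNCALIBRATED


def _read_dicom(path: Path) -> SeriesRecord:
    import pydicom

    files = sorted(p for p in path.iterdir() if p.suffix.lower() in {".dcm", ".ima"})
    if not files:
        files = sorted(p for p in path.iterdir() if p.is_file())
    if not files:
        raise FileNotFoundError(f"no DICOM files in {path}")
    slices = []
    manufacturer_tag: Optional[str] = None
    for i, f in enumerate(files):
        ds = pydicom.dcmread(f)
        missing = [
            tag
            for tag in ("PixelSpacing", "SliceThickness", "ImagePositionPatient")
            if getattr(ds, tag, None) is None
        ]
        if missing:
            raise ValueError(f"slice {i} ({f.name}) is missing tags: {', '.join(missing)}")
        image = ds.pixel_array
        geometry = SliceGeometry(
            pixel_spacing_row=float(ds.PixelSpacing[0]),
            pixel_spacing_col=float(ds.PixelSpacing[1]),
            slice_thickness=float(ds.SliceThickness),
            slice_position=float(ds.ImagePositionPatient[2]),
            rows=image.shape[0],
            cols=image.shape[1],
        )
        slices.append(SliceRecord(image=image, geometry=geometry))
        manufacturer_tag = manufacturer_tag or getattr(ds, "Manufacturer", None)
    return SeriesRecord(slices=slices, manufacturer=map_manufacturer(manufacturer_tag))


def read_series(path: str | Path, dialect: str = "sidecar") -> SeriesRecord:
    """Read a slice series from disk.

    Slices are returned sorted by ascending ``slice_position``.  A slice with
    incomplete geometry, or a duplicated position, is a hard error naming the
    offending slice.
    """
    path = Path(path)
    if dialect == "sidecar":
        return _read_sidecar(path)
    if dialect == "dicom":
        return _read_dicom(path)
    raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# machine-readable study report
# ---------------------------------------------------------------------------

def write_report(measures, flags, path: str | Path, *, thresholds=None,
                 calibration_id: Optional[str] = None) -> None:
    """Write the study report: raw + calibrated + indexed values, one boolean
    per diagnostic flag, an ``abnormal_any`` rollup, and provenance (the
    thresholds used and the calibration model id)."""
    from dataclasses import asdict

    flag_dict = {k: bool(v) for k, v in asdict(flags).items()}
    doc = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "measures": asdict(measures),
        "flags": flag_dict,
        "abnormal_any": any(flag_dict.values()),
        "provenance": {
            "thresholds": asdict(thresholds) if thresholds is not None else None,
            "calibration_model": calibration_id,
        },
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_report(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
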