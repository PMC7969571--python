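"""Clinical measures from the 3D model, per-manufacturer calibration, and
threshold-based abnormality classification.

Measures: LV/RV end-diastolic volume (the cavity-class volumes, ml), LV mass
(wall volume × 1.05 g/ml, the standard myocardial density convention),
ascending-aortic diameter (mm), and pleural-fluid volume (ml).  Volumes and
diameters are indexed by body surface area (BSA, Mosteller by default), and
the mass:volume ratio is LVMi/LVEDVi.

Calibration: the raw geometric measurements carry manufacturer-dependent
systematic bias relative to clinically reported values, so a simple linear
regression (raw → final) is fitted separately per scanner manufacturer and
per measure; an unknown manufacturer maps to an "uncalibrated" category for
which calibration is the identity.  Calibration operates on the indexed
measures; the mass:volume ratio is calibrated directly by default (it has
its own fitted model) but can instead be recomputed from the calibrated
components.

Classification uses strict ">" against published BSA-indexed cut-offs:
LVEDVi > 94 ml/m² (LV dilatation), RVEDVi > 98 ml/m² (RV dilatation),
LVMi > 83.5 g/m² (LV hypertrophy), mass:volume ratio > 0.84.  The indexed
aortic-diameter and pleural-fluid cut-offs have no published value and are
required configuration; when unset, the corresponding flag is never raised.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from scipy import stats
from skimage import measure as sk_measure

from .imaging_io import LabelClass, MANUFACTURER_UNCALIBRATED
from .reconstruction import LabelVolume, structure_volume

MYOCARDIAL_DENSITY_G_PER_ML = 1.05

#: measures that pass through per-manufacturer calibration
CALIBRATED_MEASURES = ("lvedvi", "rvedvi", "lvmi", "mass_volume_ratio", "asc_aorta_i")


def bsa(height_cm: float, weight_kg: float, formula: str = "mosteller") -> float:
    """Body surface area in m² from height (cm) and weight (kg).

    Mosteller: sqrt(height × weight / 3600); Du Bois available as an
    alternative convention.
    """
    if height_cm <= 0 or weight_kg <= 0:
        raise ValueError("height and weight must be > 0")
    if formula == "mosteller":
        return math.sqrt(height_cm * weight_kg / 3600.0)
    if formula == "dubois":
        return 0.007184 * height_cm**0.725 * weight_kg**0.425
    raise ValueError(f"unknown BSA formula {formula!r}")


@dataclass
class StudyMeasures:
    """Raw and BSA-indexed scalar measurements for one study."""

    lvedv_ml: float
    rvedv_ml: float
    lv_wall_volume_ml: float
    lv_mass_g: float
    pleural_fluid_ml: float
    bsa_m2: float
    asc_aorta_diameter_mm: Optional[float] = None
    lvedvi: float = 0.0
    rvedvi: float = 0.0
    lvmi: float = 0.0
    asc_aorta_i: Optional[float] = None
    mass_volume_ratio: Optional[float] = None


def ascending_aorta_diameter(volume: LabelVolume) -> Optional[float]:
    """Maximum equivalent-circle diameter of the ascending aorta, in mm.

    On each axial plane where the aorta class splits into >= 2 connected
    components, the most anterior component (smallest mean row coordinate)
    is taken as the ascending aorta and its equivalent-circle diameter is
    2·sqrt(area/π).  Returns the maximum over qualifying planes, or ``None``
    ("not measurable", distinct from 0) when the aorta is absent or never
    splits into two components.
    """
    occ = volume.occupancy_of(int(LabelClass.aorta))
    dz, dy, dx = volume.voxel_size
    pixel_area = dy * dx
    best: Optional[float] = None
    for k in range(volume.shape[0]):
        mask = occ[k] > 0.5
        if not mask.any():
            continue
        comp, n = sk_measure.label(mask, return_num=True)
        if n < 2:
            continue
        anterior_label = min(
            range(1, n + 1), key=lambda lbl: np.nonzero(comp == lbl)[0].mean()
        )
        area = float(np.count_nonzero(comp == anterior_label)) * pixel_area
        diameter = 2.0 * math.sqrt(area / math.pi)
        if best is None or diameter > best:
            best = diameter
    return best


def derive_measures(volume: LabelVolume, bsa_m2: float) -> StudyMeasures:
    """Raw structure volumes → :class:`StudyMeasures` with BSA indexing."""
    if bsa_m2 <= 0:
        raise ValueError("BSA must be > 0")
    lvedv = structure_volume(volume, LabelClass.lv_cavity)
    rvedv = structure_volume(volume, LabelClass.rv_cavity)
    wall = structure_volume(volume, LabelClass.lv_wall)
    mass = wall * MYOCARDIAL_DENSITY_G_PER_ML
    pleural = structure_volume(volume, LabelClass.pleural_effusion)
    diameter = ascending_aorta_diameter(volume)
    lvedvi = lvedv / bsa_m2
    lvmi = mass / bsa_m2
    return StudyMeasures(
        lvedv_ml=lvedv,
        rvedv_ml=rvedv,
        lv_wall_volume_ml=wall,
        lv_mass_g=mass,
        pleural_fluid_ml=pleural,
        bsa_m2=bsa_m2,
        asc_aorta_diameter_mm=diameter,
        lvedvi=lvedvi,
        rvedvi=rvedv / bsa_m2,
        lvmi=lvmi,
        asc_aorta_i=None if diameter is None else diameter / bsa_m2,
        mass_volume_ratio=None if lvedvi <= 0 else lvmi / lvedvi,
    )


# ---------------------------------------------------------------------------
# per-manufacturer linear calibration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CalibrationEntry:
    slope: float
    intercept: float
    n: int
    r_squared: float

    def apply(self, value: float) -> float:
        return self.slope * value + self.intercept


@dataclass
class CalibrationModel:
    """OLS raw → final mappings keyed by (manufacturer, measure)."""

    entries: Dict[Tuple[str, str], CalibrationEntry] = field(default_factory=dict)
    model_id: str = "unnamed"

    def get(self, manufacturer: str, measure: str) -> Optional[CalibrationEntry]:
        return self.entries.get((manufacturer, measure))

    def to_json(self, path) -> None:
        doc = {
            "model_id": self.model_id,
            "entries": {
                f"{man}:{meas}": {
                    "slope": e.slope, "intercept": e.intercept,
                    "n": e.n, "r_squared": e.r_squared,
                }
                for (man, meas), e in self.entries.items()
            },
        }
        Path(path).write_text(json.dumps(doc, indent=1))

    @classmethod
    def from_json(cls, path) -> "CalibrationModel":
        doc = json.loads(Path(path).read_text())
        entries = {}
        for key, e in doc["entries"].items():
            man, meas = key.split(":", 1)
            entries[(man, meas)] = CalibrationEntry(
                slope=e["slope"], intercept=e["intercept"],
                n=e["n"], r_squared=e["r_squared"],
            )
        return cls(entries=entries, model_id=doc.get("model_id", "unnamed"))


def fit_calibration(pairs: Sequence[Tuple[float, float]], manufacturer: str,
                    measure: str) -> CalibrationEntry:
    """Ordinary least squares on (raw, final) pairs for one manufacturer and
    measure; requires >= 3 pairs and nonzero variance in the raw values."""
    if len(pairs) < 3:
        raise ValueError("calibration needs >= 3 (raw, final) pairs")
    raw = np.array([p[0] for p in pairs], dtype=float)
    final = np.array([p[1] for p in pairs], dtype=float)
    if np.ptp(raw) == 0:
        raise ValueError("raw values have zero variance; cannot fit a line")
    fit = stats.linregress(raw, final)
    return CalibrationEntry(
        slope=float(fit.slope), intercept=float(fit.intercept),
        n=len(pairs), r_squared=float(fit.rvalue**2),
    )


def apply_calibration(measures: StudyMeasures, model: CalibrationModel,
                      manufacturer: str, *, mvr_mode: str = "direct") -> StudyMeasures:
    """Map each indexed measure through its fitted (slope, intercept).

    ``manufacturer == "uncalibrated"`` is the identity.  ``mvr_mode`` is
    ``"direct"`` (the mass:volume ratio has its own calibration line) or
    ``"derived"`` (recomputed as calibrated LVMi / calibrated LVEDVi).
    Raw volumes/mass are recomputed from the calibrated indexed values so
    the indexed × BSA = raw invariant is preserved.
    """
    if mvr_mode not in ("direct", "derived"):
        raise ValueError("mvr_mode must be 'direct' or 'derived'")
    if manufacturer == MANUFACTURER_UNCALIBRATED:
        return replace(measures)

    wanted = [m for m in CALIBRATED_MEASURES
              if not (m == "asc_aorta_i" and measures.asc_aorta_i is None)]
    if mvr_mode == "derived":
        wanted = [m for m in wanted if m != "mass_volume_ratio"]
    missing = [m for m in wanted if model.get(manufacturer, m) is None]
    if missing:
        raise ValueError(
            f"calibration model has no entry for manufacturer {manufacturer!r}, "
            f"measures: {', '.join(missing)}"
        )

    out = replace(measures)
    out.lvedvi = model.get(manufacturer, "lvedvi").apply(measures.lvedvi)
    out.rvedvi = model.get(manufacturer, "rvedvi").apply(measures.rvedvi)
    out.lvmi = model.get(manufacturer, "lvmi").apply(measures.lvmi)
    if measures.asc_aorta_i is not None:
        out.asc_aorta_i = model.get(manufacturer, "asc_aorta_i").apply(measures.asc_aorta_i)
    if mvr_mode == "direct":
        if measures.mass_volume_ratio is not None:
            out.mass_volume_ratio = model.get(
                manufacturer, "mass_volume_ratio"
            ).apply(measures.mass_volume_ratio)
    else:
        out.mass_volume_ratio = None if out.lvedvi <= 0 else out.lvmi / out.lvedvi

    # keep indexed × BSA == raw
    out.lvedv_ml = out.lvedvi * out.bsa_m2
    out.rvedv_ml = out.rvedvi * out.bsa_m2
    out.lv_mass_g = out.lvmi * out.bsa_m2
    out.lv_wall_volume_ml = out.lv_mass_g / MYOCARDIAL_DENSITY_G_PER_ML
    if out.asc_aorta_i is not None:
        out.asc_aorta_diameter_mm = out.asc_aorta_i * out.bsa_m2
    return out


# ---------------------------------------------------------------------------
# diagnosis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DiagnosticThresholds:
    """Abnormality cut-offs; comparisons are strict ">"."""

    lvedvi_max: float = 94.0       # ml/m²
    rvedvi_max: float = 98.0       # ml/m²
    lvmi_max: float = 83.5         # g/m²
    mvr_max: float = 0.84          # dimensionless
    aorta_i_max: Optional[float] = None   # mm/m², site configuration
    effusion_ml_min: Optional[float] = None  # ml, site configuration

    def __post_init__(self) -> None:
        for name in ("lvedvi_max", "rvedvi_max", "lvmi_max", "mvr_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class DiagnosisFlags:
    lv_dilated: bool = False
    rv_dilated: bool = False
    lv_hypertrophy: bool = False
    raised_mvr: bool = False
    aorta_dilated: bool = False
    pleural_effusion: bool = False

    def raised(self) -> frozenset:
        from dataclasses import asdict

        return frozenset(k for k, v in asdict(self).items() if v)


def diagnose(measures: StudyMeasures,
             thresholds: DiagnosticThresholds = DiagnosticThresholds()) -> DiagnosisFlags:
    """Each flag is true iff its (calibrated) measure strictly exceeds its
    cut-off; flags whose cut-off is unset, or whose measure is unmeasurable,
    stay false."""
    return DiagnosisFlags(
        lv_dilated=measures.lvedvi > thresholds.lvedvi_max,
        rv_dilated=measures.rvedvi > thresholds.rvedvi_max,
        lv_hypertrophy=measures.lvmi > thresholds.lvmi_max,
        raised_mvr=(measures.mass_volume_ratio is not None
                    and measures.mass_volume_ratio > thresholds.mvr_max),
        aorta_dilated=(thresholds.aorta_i_max is not None
                       and measures.asc_aorta_i is not None
                       and measures.asc_aorta_i > thresholds.aorta_i_max),
        pleural_effusion=(thresholds.effusion_ml_min is not None
                          and measures.pleural_fluid_ml > thresholds.effusion_ml_min),
    )
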