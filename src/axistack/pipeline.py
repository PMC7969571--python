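"""End-to-end convenience: slices → segmentation → 3D model → measures → flags."""

from __future__ import annotations

from typing import Optional

from .imaging_io import MANUFACTURER_UNCALIBRATED, SeriesRecord
from .quantification import (
    CalibrationModel,
    DiagnosticThresholds,
    DiagnosisFlags,
    StudyMeasures,
    apply_calibration,
    bsa as compute_bsa,
    derive_measures,
    diagnose,
)
from .reconstruction import LabelVolume, assemble
from .segmentation import Segmenter, segment_series


def analyze_study(series: SeriesRecord, segmenter: Segmenter,
                  thresholds: DiagnosticThresholds = DiagnosticThresholds(),
                  calibration: Optional[CalibrationModel] = None,
                  *, max_dz_mm: float = 2.0):
    """Run the whole pipeline on one study.

    BSA is taken from the series if present, otherwise computed from
    height/weight.  Calibration is applied when a model is given and the
    series' manufacturer is a calibrated category.  Returns
    ``(measures, flags, volume)``.
    """
    if series.bsa is not None:
        bsa_m2 = series.bsa
    elif series.height_cm is not None and series.weight_kg is not None:
        bsa_m2 = compute_bsa(series.height_cm, series.weight_kg)
    else:
        raise ValueError("series provides neither BSA nor height/weight")

    labelled = segment_series(series, segmenter)
    volume = assemble(labelled, max_dz_mm=max_dz_mm)
    measures = derive_measures(volume, bsa_m2)
    if calibration is not None and series.manufacturer != MANUFACTURER_UNCALIBRATED:
        measures = apply_calibration(measures, calibration, series.manufacturer)
    flags = diagnose(measures, thresholds)
    return measures, flags, volume
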