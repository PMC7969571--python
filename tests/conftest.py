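"""Shared fixtures: phantom builds and end-to-end pipeline runs are expensive,
so they are session-scoped and computed lazily."""

from __future__ import annotations

import numpy as np
import pytest

import axistack as ax
from axistack.phantom import (
    EXPECTED_FLAGS,
    PRESET_AORTA_I_MAX,
    PRESET_EFFUSION_ML_MIN,
    PRESETS,
    preset_spec,
)
from axistack.quantification import DiagnosticThresholds

PRESET_THRESHOLDS = DiagnosticThresholds(
    aorta_i_max=PRESET_AORTA_I_MAX, effusion_ml_min=PRESET_EFFUSION_ML_MIN
)


@pytest.fixture(scope="session")
def preset_builds():
    """name → (label_volume at 1 mm, truth) for all five diagnostic fixtures."""
    out = {}
    for name in PRESETS:
        out[name] = ax.build_phantom(preset_spec(name), resolution_mm=1.0)
    return out


@pytest.fixture(scope="session")
def e2e_results(preset_builds):
    """Oracle-segmented end-to-end pipeline runs at 2 mm slicing:
    name → (measures, flags, reconstructed volume, truth)."""
    out = {}
    for name, (volume, truth) in preset_builds.items():
        spec = preset_spec(name)
        slices = ax.slice_phantom(volume, thickness_mm=2.0, gap_mm=0.0, pixel_spacing_mm=2.0)
        rendered = ax.render_slices(slices, spec.intensity_map, noise_sd=0.0, seed=0)
        series = ax.SeriesRecord(slices=rendered, bsa=truth.bsa_m2)
        oracle = ax.OracleSegmenter.from_series(series)
        measures, flags, rec = ax.analyze_study(series, oracle, PRESET_THRESHOLDS)
        out[name] = (measures, flags, rec, truth)
    return out


@pytest.fixture(scope="session")
def phantom_slice_pool():
    """250 rendered slices pooled across the five presets (noise sd 5),
    shuffled deterministically — the training corpus for the lightweight
    segmenter."""
    records = []
    for i, name in enumerate(PRESETS):
        spec = preset_spec(name)
        volume, _ = ax.build_phantom(spec, resolution_mm=2.0)
        slices = ax.slice_phantom(volume, thickness_mm=4.0, gap_mm=0.0, pixel_spacing_mm=2.0)
        records.extend(ax.render_slices(slices, spec.intensity_map, noise_sd=5.0, seed=100 + i))
    rng = np.random.default_rng(42)
    perm = rng.permutation(len(records))
    return [records[i] for i in perm]
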