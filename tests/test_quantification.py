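"""BSA, measure derivation, aortic diameter, calibration, diagnosis."""

import numpy as np
import pytest

from axistack.imaging_io import LabelClass
from axistack.quantification import (
    CalibrationModel,
    DiagnosticThresholds,
    StudyMeasures,
    apply_calibration,
    ascending_aorta_diameter,
    bsa,
    derive_measures,
    diagnose,
    fit_calibration,
)
from axistack.reconstruction import LabelVolume


@pytest.mark.parametrize(
    "height, weight, expected",
    [(170.0, 70.0, np.sqrt(11900.0 / 3600.0)), (180.0, 80.0, 2.0), (100.0, 36.0, 1.0)],
)
def test_mosteller_bsa(height, weight, expected):
    assert bsa(height, weight) == pytest.approx(expected, abs=1e-12)


def test_bsa_rejects_nonpositive():
    with pytest.raises(ValueError):
        bsa(0.0, 70.0)


def _volume_with(classes_ml, voxel=1.0):
    """Build a LabelVolume whose classes occupy given whole-voxel volumes,
    laid out in disjoint runs of voxels."""
    shape = (80, 50, 50)
    flat_len = int(np.prod(shape))
    occupancy = {}
    cursor = 0
    for cls, ml in classes_ml.items():
        n_vox = int(round(ml * 1000.0 / voxel**3))
        if cursor + n_vox > flat_len:
            raise AssertionError("test volume too small")
        occ = np.zeros(flat_len, dtype=np.float32)
        occ[cursor : cursor + n_vox] = 1.0
        cursor += n_vox
        occupancy[int(cls)] = occ.reshape(shape)
    return LabelVolume(shape=shape, voxel_size=(voxel,) * 3, occupancy=occupancy)


def test_derive_measures_density_and_indexing():
    volume = _volume_with({LabelClass.lv_wall: 10.0, LabelClass.lv_cavity: 18.0,
                           LabelClass.rv_cavity: 12.0})
    m = derive_measures(volume, bsa_m2=2.0)
    assert m.lv_mass_g == pytest.approx(10.0 * 1.05)
    assert m.lvedvi == pytest.approx(9.0)
    assert m.rvedvi == pytest.approx(6.0)
    assert m.mass_volume_ratio == pytest.approx(m.lvmi / m.lvedvi)
    # indexed × BSA == raw
    assert m.lvedvi * m.bsa_m2 == pytest.approx(m.lvedv_ml, abs=1e-9)
    assert m.lvmi * m.bsa_m2 == pytest.approx(m.lv_mass_g, abs=1e-9)


def test_indexing_invariant_on_random_volumes():
    rng = np.random.default_rng(0)
    for _ in range(20):
        volume = _volume_with({
            LabelClass.lv_wall: float(rng.uniform(1, 30)),
            LabelClass.lv_cavity: float(rng.uniform(1, 40)),
            LabelClass.rv_cavity: float(rng.uniform(1, 40)),
            LabelClass.pleural_effusion: float(rng.uniform(0.1, 20)),
        })
        b = float(rng.uniform(1.2, 2.4))
        m = derive_measures(volume, b)
        assert m.lvedvi * b == pytest.approx(m.lvedv_ml, abs=1e-9)
        assert m.rvedvi * b == pytest.approx(m.rvedv_ml, abs=1e-9)
        assert m.lvmi * b == pytest.approx(m.lv_mass_g, abs=1e-9)


# ---------------------------------------------------------------------------
# ascending aorta diameter
# ---------------------------------------------------------------------------

def _aorta_volume(radii_anterior, radius_posterior=10.0, voxel=1.0):
    """Two circular cross-sections per plane: anterior (ascending) at the top
    rows, posterior (descending) lower down."""
    shape = (5, 120, 120)
    occ = np.zeros(shape, dtype=np.float32)
    yy, xx = np.mgrid[0:shape[1], 0:shape[2]].astype(float)
    yy = (yy + 0.5) * voxel
    xx = (xx + 0.5) * voxel
    for k in range(shape[0]):
        r_a = radii_anterior[k] if k < len(radii_anterior) else radii_anterior[-1]
        if r_a > 0:
            occ[k][(xx - 60) ** 2 + (yy - 30) ** 2 <= r_a**2] = 1.0
        if radius_posterior > 0:
            occ[k][(xx - 60) ** 2 + (yy - 90) ** 2 <= radius_posterior**2] = 1.0
    return LabelVolume(shape=shape, voxel_size=(voxel,) * 3,
                       occupancy={int(LabelClass.aorta): occ})


def test_ascending_diameter_takes_most_anterior_component():
    volume = _aorta_volume([15.0, 15.0, 15.0])
    d = ascending_aorta_diameter(volume)
    assert d == pytest.approx(30.0, abs=1.0)  # ±1 voxel width


def test_single_component_not_measurable():
    volume = _aorta_volume([0.0, 0.0, 0.0], radius_posterior=12.0)
    assert ascending_aorta_diameter(volume) is None


def test_absent_aorta_not_measurable():
    volume = LabelVolume(shape=(4, 10, 10), voxel_size=(1.0, 1.0, 1.0))
    assert ascending_aorta_diameter(volume) is None


def test_equivalent_circle_diameter_from_area():
    """A plane whose anterior component has area π·12.5² mm² scores 25 mm."""
    shape = (1, 100, 100)
    occ = np.zeros(shape, dtype=np.float32)
    n_pixels = int(round(np.pi * 12.5**2))
    occ[0, :20, :].flat[:n_pixels] = 1.0     # anterior blob, arbitrary shape
    occ[0, 60:70, 40:50] = 1.0               # posterior second component
    volume = LabelVolume(shape=shape, voxel_size=(1.0, 1.0, 1.0),
                         occupancy={int(LabelClass.aorta): occ})
    assert ascending_aorta_diameter(volume) == pytest.approx(25.0, abs=0.05)


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

def test_ols_exact_on_a_line():
    raw = np.linspace(50, 150, 10)
    pairs = list(zip(raw, 1.2 * raw - 4.0))
    entry = fit_calibration(pairs, "A", "lvedvi")
    assert entry.slope == pytest.approx(1.2, abs=1e-9)
    assert entry.intercept == pytest.approx(-4.0, abs=1e-9)
    assert entry.r_squared == pytest.approx(1.0)


def test_ols_identity_when_raw_equals_final():
    raw = [80.0, 95.0, 120.0, 60.0]
    entry = fit_calibration(list(zip(raw, raw)), "A", "lvedvi")
    assert (entry.slope, entry.intercept) == (pytest.approx(1.0), pytest.approx(0.0))


def test_ols_matches_normal_equations():
    """Independent closed-form check: slope = Sxy/Sxx, intercept = ȳ − b·x̄."""
    rng = np.random.default_rng(1)
    x = rng.uniform(40, 160, size=30)
    y = 1.07 * x - 3.0 + rng.normal(0, 2.0, size=30)
    entry = fit_calibration(list(zip(x, y)), "A", "lvedvi")
    sxx = np.sum((x - x.mean()) ** 2)
    sxy = np.sum((x - x.mean()) * (y - y.mean()))
    assert entry.slope == pytest.approx(sxy / sxx, abs=1e-12)
    assert entry.intercept == pytest.approx(y.mean() - sxy / sxx * x.mean(), abs=1e-9)


def test_ols_requires_variance_and_three_points():
    with pytest.raises(ValueError, match="variance"):
        fit_calibration([(1.0, 2.0), (1.0, 3.0), (1.0, 4.0)], "A", "lvedvi")
    with pytest.raises(ValueError, match=">= 3"):
        fit_calibration([(1.0, 2.0), (2.0, 3.0)], "A", "lvedvi")


def test_noisy_bias_recovery_at_n50():
    """Injected bias (1.1, −5) with sd-2 noise: fitted slope lands in
    [1.05, 1.15] at n = 50."""
    rng = np.random.default_rng(7)
    truth = rng.uniform(50, 160, size=50)
    final = 1.1 * truth - 5.0 + rng.normal(0, 2.0, size=50)
    entry = fit_calibration(list(zip(truth, final)), "A", "lvedvi")
    assert 1.05 <= entry.slope <= 1.15


def _measures(**kw):
    base = dict(lvedv_ml=200.0, rvedv_ml=140.0, lv_wall_volume_ml=100.0,
                lv_mass_g=105.0, pleural_fluid_ml=0.0, bsa_m2=2.0,
                asc_aorta_diameter_mm=36.0, lvedvi=100.0, rvedvi=70.0,
                lvmi=52.5, asc_aorta_i=18.0, mass_volume_ratio=0.525)
    base.update(kw)
    return StudyMeasures(**base)


def _model(slope, intercept, manufacturer="A"):
    model = CalibrationModel(model_id="test")
    for measure in ("lvedvi", "rvedvi", "lvmi", "mass_volume_ratio", "asc_aorta_i"):
        model.entries[(manufacturer, measure)] = fit_calibration(
            [(x, slope * x + intercept) for x in (10.0, 50.0, 90.0)],
            manufacturer, measure,
        )
    return model


def test_apply_identity_model():
    m = _measures()
    out = apply_calibration(m, _model(1.0, 0.0), "A")
    assert out == m


def test_apply_affine_model():
    out = apply_calibration(_measures(), _model(1.1, -5.0), "A")
    assert out.lvedvi == pytest.approx(105.0)
    assert out.lvedv_ml == pytest.approx(210.0)  # invariant re-established


def test_uncalibrated_manufacturer_is_identity():
    m = _measures()
    assert apply_calibration(m, CalibrationModel(), "uncalibrated") == m


def test_missing_entry_lists_the_measure():
    model = _model(1.0, 0.0)
    del model.entries[("A", "rvedvi")]
    with pytest.raises(ValueError, match="rvedvi"):
        apply_calibration(_measures(), model, "A")


def test_fit_then_apply_round_trip():
    """Calibration fitted on a noiseless generating line maps raw values to
    the line exactly."""
    out = apply_calibration(_measures(lvedvi=100.0), _model(1.2, -4.0), "A")
    assert out.lvedvi == pytest.approx(1.2 * 100.0 - 4.0, abs=1e-9)


def test_calibration_json_round_trip(tmp_path):
    model = _model(1.1, -5.0)
    model.to_json(tmp_path / "calib.json")
    back = CalibrationModel.from_json(tmp_path / "calib.json")
    assert back.entries == model.entries


# ---------------------------------------------------------------------------
# diagnosis
# ---------------------------------------------------------------------------

def test_strict_threshold_boundaries():
    assert diagnose(_measures(lvedvi=95.0)).lv_dilated is True
    assert diagnose(_measures(lvedvi=94.0)).lv_dilated is False
    assert diagnose(_measures(mass_volume_ratio=0.85)).raised_mvr is True
    assert diagnose(_measures(mass_volume_ratio=0.84)).raised_mvr is False
    assert diagnose(_measures(rvedvi=98.5)).rv_dilated is True
    assert diagnose(_measures(lvmi=83.6)).lv_hypertrophy is True


def test_unset_cutoffs_never_flag():
    m = _measures(asc_aorta_i=40.0, pleural_fluid_ml=500.0)
    flags = diagnose(m, DiagnosticThresholds())
    assert flags.aorta_dilated is False and flags.pleural_effusion is False
    thr = DiagnosticThresholds(aorta_i_max=21.0, effusion_ml_min=50.0)
    flags = diagnose(m, thr)
    assert flags.aorta_dilated is True and flags.pleural_effusion is True


def test_diagnosis_monotone_in_each_measure():
    """Raising a measure never clears its flag."""
    rng = np.random.default_rng(2)
    thr = DiagnosticThresholds(aorta_i_max=21.0, effusion_ml_min=50.0)
    fields = ["lvedvi", "rvedvi", "lvmi", "mass_volume_ratio", "asc_aorta_i",
              "pleural_fluid_ml"]
    flag_of = dict(zip(fields, ["lv_dilated", "rv_dilated", "lv_hypertrophy",
                                "raised_mvr", "aorta_dilated", "pleural_effusion"]))
    for _ in range(50):
        field = fields[int(rng.integers(len(fields)))]
        lo, hi = sorted(rng.uniform(0, 200, size=2))
        f_lo = getattr(diagnose(_measures(**{field: lo}), thr), flag_of[field])
        f_hi = getattr(diagnose(_measures(**{field: hi}), thr), flag_of[field])
        assert f_hi >= f_lo
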