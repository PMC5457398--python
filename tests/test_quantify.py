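"""Quantification protocol: specificity gates, calibration, consensus."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from srmtdm.quantify import (
    CalibrationCurve,
    PeptideMeasurement,
    accept_calibration_levels,
    back_calculate,
    coelution_check,
    fit_calibration,
    measure_peptide,
    quantify_sample,
    transition_ratio_check,
)
from srmtdm.chromatogram import Peak
from srmtdm.simulate import SimConfig, simulate_sample_chromatograms

LEVELS9 = tuple(np.geomspace(1.0, 1000.0, 9))


def make_peak(rt, found=True):
    return Peak(apex_rt=rt, area=100.0, left_bound=rt - 0.1, right_bound=rt + 0.1,
                height=50.0, signal_to_noise=100.0, found=found)


def make_measurement(ratio=1.0, qual_scale=1.0, heavy_quant=1000.0, pid="HT4"):
    """A measurement with light qualifier ratios = qual_scale × heavy ratios."""
    light_quant = ratio * heavy_quant
    quals = {
        851.6: (0.5 * light_quant * qual_scale, 0.5 * heavy_quant),
        759.0: (0.3 * light_quant * qual_scale, 0.3 * heavy_quant),
    }
    return PeptideMeasurement(
        sample_id="s", peptide_id=pid,
        light_quantifier_area=light_quant, heavy_quantifier_area=heavy_quant,
        qualifier_areas=quals, light_rt=8.8, heavy_rt=8.8,
    )


def exact_curve(slope=0.01, intercept=0.0, levels=LEVELS9, pid="HT4"):
    pts = [(x, intercept + slope * x) for x in levels]
    return fit_calibration(pts, peptide_id=pid)


# --- specificity gates -----------------------------------------------------

@pytest.mark.parametrize("delta, ok", [(0.05, True), (0.10, True), (0.15, False)])
def test_coelution_boundaries(delta, ok):
    assert coelution_check(make_peak(8.8), make_peak(8.8 + delta)) is ok


def test_coelution_missing_peak_fails_quietly():
    assert coelution_check(make_peak(8.8), make_peak(8.8, found=False)) is False


@pytest.mark.parametrize("scale, ok", [(1.0, True), (1.30, False), (0.75, True), (1.25, True)])
def test_transition_ratio_boundaries(scale, ok):
    assert transition_ratio_check(make_measurement(qual_scale=scale)) is ok


def test_transition_ratio_zero_heavy_fails():
    m = make_measurement()
    m.heavy_quantifier_area = 0.0
    assert transition_ratio_check(m) is False


# --- calibration -----------------------------------------------------------

def test_exact_fit_is_unweighted_identity():
    curve = exact_curve()
    assert curve.slope == pytest.approx(0.01, rel=1e-9)
    assert curve.intercept == pytest.approx(0.0, abs=1e-12)
    assert curve.r2 == pytest.approx(1.0, abs=1e-12)
    assert curve.weighting == "1"  # tie broken to the simplest scheme
    assert curve.curve_valid


def test_weighting_selection_tracks_variance_structure():
    """CV-constant noise favours 1/x², constant-variance noise favours 1."""
    rng = np.random.default_rng(42)
    x = np.array(LEVELS9)
    het = hom = 0
    n = 50
    for _ in range(n):
        y = 0.01 * x * (1 + 0.05 * rng.standard_normal(x.size))
        het += fit_calibration(list(zip(x, y))).weighting == "1/x^2"
        y = 0.01 * x + 0.05 * rng.standard_normal(x.size)
        hom += fit_calibration(list(zip(x, np.maximum(y, 1e-9)))).weighting == "1"
    assert het / n >= 0.7
    assert hom / n >= 0.5


def test_fit_requires_six_levels_and_positive_nominals():
    with pytest.raises(ValueError):
        fit_calibration([(x, 0.01 * x) for x in LEVELS9[:5]])
    with pytest.raises(ValueError):
        fit_calibration([(-1.0, 0.1)] + [(x, 0.01 * x) for x in LEVELS9[:5]])
    with pytest.raises(ValueError):
        fit_calibration([(10.0, 0.1)] * 6)


def test_level_acceptance_bands():
    curve = CalibrationCurve("HT4", [], "1", slope=0.01, intercept=0.0, r2=1.0)
    # accuracy a% at nominal x needs ratio = a/100 * x * slope
    curve.levels = [(x, 0.01 * x) for x in LEVELS9]
    curve.levels[0] = (1.0, 0.01 * 1.18)  # lowest standard at 118%
    curve.levels[4] = (LEVELS9[4], 0.01 * LEVELS9[4] * 1.18)  # mid at 118%
    curve = accept_calibration_levels(curve)
    assert curve.level_accepted[0] is True  # ±20% at the LLOQ
    assert curve.level_accepted[4] is False  # ±15% elsewhere
    assert curve.curve_valid  # 8 of 9 accepted


def test_curve_invalid_when_too_many_levels_fail():
    curve = CalibrationCurve("HT4", [], "1", slope=0.01, intercept=0.0, r2=1.0)
    curve.levels = [(x, 0.01 * x) for x in LEVELS9]
    for i in (2, 4, 6, 8):
        x = curve.levels[i][0]
        curve.levels[i] = (x, 0.01 * x * 1.3)
    curve = accept_calibration_levels(curve)
    assert sum(curve.level_accepted) == 5
    assert not curve.curve_valid  # 5/9 < 75%


def test_back_calculate():
    curve = exact_curve()
    assert back_calculate(curve, 1.0) == pytest.approx(100.0, rel=1e-9)
    assert back_calculate(curve, curve.intercept) == pytest.approx(0.0, abs=1e-9)
    # round trip: each level's ratio maps back to its nominal
    for nominal, ratio in curve.levels:
        assert back_calculate(curve, ratio) == pytest.approx(nominal, rel=1e-9)


def test_back_calculate_requires_valid_curve():
    curve = exact_curve()
    curve.curve_valid = False
    with pytest.raises(ValueError):
        back_calculate(curve, 1.0)


# --- consensus -------------------------------------------------------------

def curves_for_consensus():
    return {"HT4": exact_curve(pid="HT4"), "LT3": exact_curve(pid="LT3")}


def test_consensus_concordant():
    res = quantify_sample(
        make_measurement(ratio=0.49, pid="HT4"),
        make_measurement(ratio=0.51, pid="LT3"),
        curves_for_consensus(),
    )
    assert res.consensus_conc == pytest.approx(50.0, rel=1e-9)
    assert res.concordance_pct == pytest.approx(4.0, rel=1e-9)
    assert res.valid and not res.qc_flags


def test_consensus_withheld_when_discordant():
    res = quantify_sample(
        make_measurement(ratio=0.40, pid="HT4"),
        make_measurement(ratio=0.50, pid="LT3"),
        curves_for_consensus(),
    )
    assert res.concordance_pct == pytest.approx(100 * 10 / 45, rel=1e-6)  # 22.2%
    assert res.consensus_conc is None and not res.valid
    assert "discordant_peptides" in res.qc_flags


def test_consensus_withheld_on_failed_specificity():
    bad = make_measurement(ratio=0.50, qual_scale=1.4, pid="HT4")
    bad.transition_ratio_ok = transition_ratio_check(bad)
    res = quantify_sample(bad, make_measurement(ratio=0.50, pid="LT3"),
                          curves_for_consensus())
    assert "transition_ratio:HT4" in res.qc_flags
    assert res.consensus_conc is None and not res.valid


def test_missing_curve_raises():
    with pytest.raises(KeyError):
        quantify_sample(make_measurement(pid="HT4"), make_measurement(pid="LT3"),
                        {"HT4": exact_curve()})


@given(st.floats(1e-3, 1e3))
def test_response_ratio_gain_invariance(gain):
    """Rescaling every area in a sample leaves the response ratio unchanged."""
    m = make_measurement(ratio=0.7)
    scaled = make_measurement(ratio=0.7, heavy_quant=1000.0 * gain)
    assert scaled.response_ratio == pytest.approx(m.response_ratio, rel=1e-9)


@given(st.floats(0.1, 200.0), st.floats(0.1, 200.0))
def test_concordance_symmetry(a, b):
    curves = curves_for_consensus()
    r1 = quantify_sample(make_measurement(ratio=a * 0.01, pid="HT4"),
                         make_measurement(ratio=b * 0.01, pid="LT3"), curves)
    r2 = quantify_sample(make_measurement(ratio=b * 0.01, pid="HT4"),
                         make_measurement(ratio=a * 0.01, pid="LT3"), curves)
    assert r1.concordance_pct == pytest.approx(r2.concordance_pct, rel=1e-9)


def test_end_to_end_spiked_sample_within_15pct(assay):
    """Simulator sample at 100 µg/mL quantifies within 15% of truth."""
    cfg = SimConfig(seed=7)
    chroms = simulate_sample_chromatograms(assay, 100.0, config=cfg)
    curves = {}
    rng = np.random.default_rng(7)
    from srmtdm.simulate import simulate_calibration_batch

    man, std_chroms = simulate_calibration_batch(assay, config=cfg, rng=rng)
    for pep in assay:
        levels = sorted(
            (row.nominal_conc, measure_peptide(std_chroms[row.sample_id], pep).response_ratio)
            for row in man.itertuples()
        )
        curves[pep.peptide_id] = fit_calibration(levels, peptide_id=pep.peptide_id)
    res = quantify_sample(
        measure_peptide(chroms, assay[0]), measure_peptide(chroms, assay[1]), curves
    )
    assert res.valid
    assert res.consensus_conc == pytest.approx(100.0, rel=0.15)
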