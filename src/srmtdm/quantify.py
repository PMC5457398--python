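"""Stable-isotope-dilution quantification of cetuximab from SRM peaks.

The measurement unit is the response ratio: light (analyte) quantifier
peak area divided by the co-eluting heavy (SIL internal standard)
quantifier area, which cancels recovery and ionization variation.  Two
specificity gates precede quantification: (i) light and heavy apexes must
co-elute within 0.1 min; (ii) each qualifier/quantifier relative ion ratio
on the light channel must match its heavy-channel counterpart within ±25%.

Calibration regresses response ratio on nominal concentration by weighted
least squares; the weighting factor (1, 1/x or 1/x²) is chosen by
comparing the Gaussian profile likelihood of the three variance models, so
CV-constant data select 1/x² and constant-variance data select the
unweighted fit.  Standards must back-calculate within ±15% of nominal
(±20% at the lowest level); a curve is valid when at least 75% of levels
and at least 6 levels are accepted.

A sample's concentration is the mean of the HT4 and LT3 determinations,
reported only when the two agree within 20%.

All acceptance boundaries in this module are inclusive: "within 0.1 min",
"±25%", "±15/20%" and "below 20%" admit values exactly at the limit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import statsmodels.api as sm

from .assay import HEAVY, LIGHT, PeptideAssay
from .chromatogram import Chromatogram, Peak, detect_peak

__all__ = [
    "PeptideMeasurement",
    "CalibrationCurve",
    "SampleResult",
    "measure_peptide",
    "coelution_check",
    "transition_ratio_check",
    "fit_calibration",
    "accept_calibration_levels",
    "back_calculate",
    "quantify_sample",
    "WEIGHT_SCHEMES",
]

#: Candidate weighting factors in preference order (ties go to the simplest).
WEIGHT_SCHEMES = ("1", "1/x", "1/x^2")

COELUTION_TOL_MIN = 0.1
TRANSITION_RATIO_TOL_PCT = 25.0
CONCORDANCE_LIMIT_PCT = 20.0
ACCURACY_BAND = (85.0, 115.0)
ACCURACY_BAND_LLOQ = (80.0, 120.0)

_EPS = 1e-9  # relative slack making boundary comparisons inclusive


@dataclass
class PeptideMeasurement:
    """Integrated areas and QC flags for one peptide in one sample."""

    sample_id: str
    peptide_id: str
    light_quantifier_area: float
    heavy_quantifier_area: float
    qualifier_areas: dict = field(default_factory=dict)  # product_mz -> (light, heavy)
    light_rt: float = float("nan")
    heavy_rt: float = float("nan")
    light_found: bool = True
    heavy_found: bool = True
    coelution_ok: bool = True
    transition_ratio_ok: bool = True

    @property
    def response_ratio(self) -> float:
        """Light/heavy quantifier area ratio; NaN when the IS is missing."""
        if self.heavy_quantifier_area <= 0:
            return float("nan")
        return self.light_quantifier_area / self.heavy_quantifier_area


@dataclass
class CalibrationCurve:
    peptide_id: str
    levels: list  # (nominal µg/mL, response ratio)
    weighting: str
    slope: float
    intercept: float
    r2: float
    back_calc_accuracy: list = field(default_factory=list)  # % of nominal
    level_accepted: list = field(default_factory=list)
    curve_valid: bool = False
    lloq_level: float = float("nan")


@dataclass
class SampleResult:
    sample_id: str
    conc_by_peptide: dict  # peptide_id -> µg/mL
    consensus_conc: float | None
    concordance_pct: float | None
    qc_flags: set = field(default_factory=set)
    valid: bool = False


# ---------------------------------------------------------------------------
# peak-level measurement

def measure_peptide(
    chroms: Sequence[Chromatogram],
    peptide: PeptideAssay,
    *,
    window: float = 0.3,
    coelution_tolerance: float = COELUTION_TOL_MIN,
) -> PeptideMeasurement:
    """Detect every transition of one peptide and assemble the measurement.

    ``chroms`` is the sample's trace set; traces belonging to other
    peptides are ignored.  Co-elution and ion-ratio checks are evaluated
    here so downstream code only reads the flags.
    """
    peaks: dict[tuple[str, float], Peak] = {}
    for ch in chroms:
        t = ch.transition
        if t.peptide_id != peptide.peptide_id:
            continue
        peaks[(t.channel, t.product_mz)] = detect_peak(ch, t.expected_rt, window)

    lq = peptide.quantifier(LIGHT)
    hq = peptide.quantifier(HEAVY)
    light_peak = peaks.get((LIGHT, lq.product_mz))
    heavy_peak = peaks.get((HEAVY, hq.product_mz))
    if light_peak is None or heavy_peak is None:
        raise ValueError(f"missing quantifier trace for {peptide.peptide_id}")

    qualifier_areas = {}
    for lt, ht in zip(peptide.qualifiers(LIGHT), peptide.qualifiers(HEAVY)):
        lp = peaks.get((LIGHT, lt.product_mz))
        hp = peaks.get((HEAVY, ht.product_mz))
        qualifier_areas[lt.product_mz] = (
            lp.area if lp is not None else float("nan"),
            hp.area if hp is not None else float("nan"),
        )

    meas = PeptideMeasurement(
        sample_id=chroms[0].sample_id if chroms else "",
        peptide_id=peptide.peptide_id,
        light_quantifier_area=light_peak.area,
        heavy_quantifier_area=heavy_peak.area,
        qualifier_areas=qualifier_areas,
        light_rt=light_peak.apex_rt,
        heavy_rt=heavy_peak.apex_rt,
        light_found=light_peak.found,
        heavy_found=heavy_peak.found,
    )
    meas.coelution_ok = coelution_check(light_peak, heavy_peak, coelution_tolerance)
    meas.transition_ratio_ok = transition_ratio_check(meas)
    return meas


def coelution_check(
    light_peak: Peak, heavy_peak: Peak, tolerance: float = COELUTION_TOL_MIN
) -> bool:
    """True iff both peaks were found and their apexes agree within the
    tolerance (boundary inclusive).  A missing peak fails rather than raises."""
    if not (light_peak.found and heavy_peak.found):
        return False
    delta = abs(light_peak.apex_rt - heavy_peak.apex_rt)
    return delta <= tolerance * (1.0 + _EPS) + 1e-12


def transition_ratio_check(
    meas: PeptideMeasurement, tolerance_pct: float = TRANSITION_RATIO_TOL_PCT
) -> bool:
    """Compare light vs heavy relative ion ratios for every qualifier.

    For each qualifier, the relative ratio is its area divided by the
    quantifier area, computed on each channel; the light value must lie
    within ±tolerance_pct of the heavy value (inclusive).  Missing areas or
    a zero heavy quantifier fail the check.
    """
    if meas.heavy_quantifier_area <= 0 or meas.light_quantifier_area <= 0:
        return False
    tol = tolerance_pct / 100.0
    for light_area, heavy_area in meas.qualifier_areas.values():
        if not (np.isfinite(light_area) and np.isfinite(heavy_area)):
            return False
        if heavy_area <= 0:
            return False
        light_rel = light_area / meas.light_quantifier_area
        heavy_rel = heavy_area / meas.heavy_quantifier_area
        if heavy_rel <= 0:
            return False
        if abs(light_rel / heavy_rel - 1.0) > tol * (1.0 + _EPS) + 1e-12:
            return False
    return True


# ---------------------------------------------------------------------------
# calibration

def _weights(scheme: str, x: np.ndarray) -> np.ndarray:
    if scheme == "1":
        return np.ones_like(x)
    if scheme == "1/x":
        return 1.0 / x
    if scheme == "1/x^2":
        return 1.0 / x**2
    raise ValueError(f"unknown weighting scheme {scheme!r}")


def fit_calibration(
    levels: Sequence[tuple[float, float]],
    candidate_weights: Sequence[str] = WEIGHT_SCHEMES,
    *,
    peptide_id: str = "",
    lloq_level: float | None = None,
) -> CalibrationCurve:
    """Weighted linear calibration with data-driven weighting selection.

    Each candidate weighting (w = 1, 1/x, 1/x²) is fit by weighted least
    squares of response ratio on nominal concentration.  The retained
    weighting maximizes the Gaussian profile likelihood of its variance
    model Var(yᵢ) = σ²/wᵢ — equivalently it minimizes
    n·log(SSR_w/n) − Σ log wᵢ — which consistently identifies whether the
    residual scatter is constant or concentration-proportional.  Ties (for
    example, exact data, where every weighting fits perfectly) resolve to
    the simplest scheme in the order 1, 1/x, 1/x².

    Back-calculated accuracies and level acceptance are filled via
    :func:`accept_calibration_levels`.
    """
    pts = [(float(x), float(y)) for x, y in levels]
    if len(pts) < 6:
        raise ValueError("calibration requires at least 6 levels")
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    if np.any(x <= 0):
        raise ValueError("nominal concentrations must be positive")
    if np.all(x == x[0]):
        raise ValueError("degenerate calibration: all nominals identical")

    n = x.size
    X = sm.add_constant(x)
    best = None
    for scheme in candidate_weights:
        w = _weights(scheme, x)
        res = sm.WLS(y, X, weights=w).fit()
        intercept, slope = float(res.params[0]), float(res.params[1])
        ssr_w = float(np.sum(w * (y - res.fittedvalues) ** 2))
        scale = float(np.sum(w * y**2))
        if ssr_w <= 0 or (scale > 0 and ssr_w / scale < 1e-24):
            score = -math.inf  # numerically perfect fit under this weighting
        else:
            score = n * math.log(ssr_w / n) - float(np.sum(np.log(w)))
        if best is None:
            best = (score, scheme, slope, intercept, float(res.rsquared))
        else:
            tol = max(abs(best[0]) * _EPS, 1e-12)
            if score < best[0] - tol:  # strict improvement; ties keep the simpler
                best = (score, scheme, slope, intercept, float(res.rsquared))

    _, scheme, slope, intercept, r2 = best
    curve = CalibrationCurve(
        peptide_id=peptide_id,
        levels=pts,
        weighting=scheme,
        slope=slope,
        intercept=intercept,
        r2=r2,
    )
    return accept_calibration_levels(curve, lloq_level)


def accept_calibration_levels(
    curve: CalibrationCurve, lloq_level: float | None = None
) -> CalibrationCurve:
    """Apply the back-calculation acceptance rules and set curve validity.

    Every standard must back-calculate to 85–115% of nominal, relaxed to
    80–120% at the lowest standard (the LLOQ); the curve is valid when at
    least 75% of the levels and at least 6 levels are accepted and the
    slope is positive.
    """
    if not curve.levels:
        raise ValueError("curve has no levels")
    if lloq_level is None:
        lloq_level = min(x for x, _ in curve.levels)
    curve.lloq_level = float(lloq_level)

    accuracies, accepted = [], []
    for nominal, ratio in curve.levels:
        bc = (ratio - curve.intercept) / curve.slope if curve.slope != 0 else math.nan
        acc = bc / nominal * 100.0
        lo, hi = ACCURACY_BAND_LLOQ if nominal <= lloq_level else ACCURACY_BAND
        ok = (
            math.isfinite(acc)
            and lo * (1 - _EPS) <= acc <= hi * (1 + _EPS)
        )
        accuracies.append(acc)
        accepted.append(bool(ok))
    curve.back_calc_accuracy = accuracies
    curve.level_accepted = accepted
    n_ok = sum(accepted)
    curve.curve_valid = (
        n_ok >= 6
        and n_ok >= 0.75 * len(accepted) - _EPS
        and curve.slope > 0
    )
    return curve


def back_calculate(curve: CalibrationCurve, ratio: float) -> float:
    """Invert the calibration: (ratio − intercept) / slope, floored at 0."""
    if not curve.curve_valid:
        raise ValueError(f"calibration curve for {curve.peptide_id!r} is not valid")
    if curve.slope == 0:
        raise ValueError("zero slope")
    return max((ratio - curve.intercept) / curve.slope, 0.0)


# ---------------------------------------------------------------------------
# sample-level consensus

def quantify_sample(
    meas_ht4: PeptideMeasurement,
    meas_lt3: PeptideMeasurement,
    curves: Mapping[str, CalibrationCurve],
) -> SampleResult:
    """Dual-peptide consensus concentration with QC gating.

    Each peptide's concentration comes from inverting its own calibration.
    The consensus is the arithmetic mean of the two, reported only when
    both specificity checks pass and the two determinations agree within
    20% (relative to their mean, boundary inclusive).  Everything else is
    recorded as a flag and ``valid`` stays False.
    """
    flags: set[str] = set()
    concs: dict[str, float] = {}
    for meas in (meas_ht4, meas_lt3):
        pid = meas.peptide_id
        if pid not in curves:
            raise KeyError(f"no calibration curve for {pid}")
        curve = curves[pid]
        if not meas.coelution_ok:
            flags.add(f"coelution:{pid}")
        if not meas.transition_ratio_ok:
            flags.add(f"transition_ratio:{pid}")
        ratio = meas.response_ratio
        if not math.isfinite(ratio):
            flags.add(f"no_is_signal:{pid}")
            continue
        raw = (ratio - curve.intercept) / curve.slope
        conc = back_calculate(curve, ratio)
        if raw < 0:
            flags.add(f"below_zero:{pid}")
        uloq = max(x for x, _ in curve.levels)
        if conc > uloq * (1 + _EPS):
            flags.add(f"above_uloq:{pid}")
        concs[pid] = conc

    consensus = None
    concordance = None
    if len(concs) == 2:
        a, b = concs[meas_ht4.peptide_id], concs[meas_lt3.peptide_id]
        m = (a + b) / 2.0
        concordance = abs(a - b) / m * 100.0 if m > 0 else float("inf")
        if concordance > CONCORDANCE_LIMIT_PCT * (1 + _EPS):
            flags.add("discordant_peptides")
    blocking = {f for f in flags if not f.startswith("below_zero")}
    if concordance is not None and not blocking:
        consensus = (concs[meas_ht4.peptide_id] + concs[meas_lt3.peptide_id]) / 2.0
    return SampleResult(
        sample_id=meas_ht4.sample_id or meas_lt3.sample_id,
        conc_by_peptide=concs,
        consensus_conc=consensus,
        concordance_pct=concordance,
        qc_flags=flags,
        valid=consensus is not None,
    )
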