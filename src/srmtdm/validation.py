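"""EMA-style bioanalytical validation statistics.

Precision is the coefficient of variation CV = SD/mean × 100 (sample SD,
n−1); accuracy is mean measured / nominal × 100.  Default acceptance is
CV ≤ 15% with accuracy in 85–115%, relaxed to 20% / 80–120% at the LLOQ.
Inter-day batteries pool all replicates across days.  Matrix effect is the
same battery across ≥ 6 independent plasma lots spiked at the LLOQ.
Selectivity requires any blank-matrix signal to stay below 20% of the
LLOQ response.  Recovery is accounted per preparation stage (digestion,
SPE, ionization) as the after/before mean peak-area-ratio, and the total
recovery is the product of the stage fractions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "QCBatteryResult",
    "RecoveryResult",
    "precision_accuracy",
    "inter_day_battery",
    "assess_matrix_effect",
    "assess_selectivity",
    "qualify_lloq",
    "assess_stability",
    "stage_recovery",
    "total_recovery",
    "assess_linearity",
]

CV_LIMIT_PCT = 15.0
CV_LIMIT_LLOQ_PCT = 20.0
ACCURACY_BAND = (85.0, 115.0)
ACCURACY_BAND_LLOQ = (80.0, 120.0)

_EPS = 1e-9  # inclusive boundaries: "lower than 15%" admits exactly 15


@dataclass
class QCBatteryResult:
    level_nominal: float  # µg/mL
    n: int
    mean: float
    sd: float
    cv_pct: float
    accuracy_pct: float
    limits: tuple  # (cv limit %, (accuracy lo %, accuracy hi %))
    passed: bool
    scope: str = "intra_day"  # intra_day | inter_day | matrix_effect | stability


@dataclass
class RecoveryResult:
    peptide_id: str
    stage: str  # digestion | spe | ionization | total
    recovery_pct: float
    cv_pct: float


def precision_accuracy(
    measured: Sequence[float],
    nominal: float,
    is_lloq: bool = False,
    *,
    scope: str = "intra_day",
) -> QCBatteryResult:
    """Precision (CV%) and accuracy (% of nominal) of replicate measurements."""
    vals = np.asarray(list(measured), dtype=float)
    if vals.size < 2:
        raise ValueError("need at least 2 replicates")
    if nominal <= 0:
        raise ValueError("nominal must be positive")
    mean = float(np.mean(vals))
    sd = float(np.std(vals, ddof=1))
    cv_limit = CV_LIMIT_LLOQ_PCT if is_lloq else CV_LIMIT_PCT
    band = ACCURACY_BAND_LLOQ if is_lloq else ACCURACY_BAND
    if mean == 0:
        return QCBatteryResult(
            nominal, vals.size, mean, sd, math.inf, 0.0,
            (cv_limit, band), False, scope,
        )
    cv = sd / mean * 100.0
    accuracy = mean / nominal * 100.0
    passed = (
        cv <= cv_limit * (1 + _EPS)
        and band[0] * (1 - _EPS) <= accuracy <= band[1] * (1 + _EPS)
    )
    return QCBatteryResult(
        nominal, int(vals.size), mean, sd, float(cv), float(accuracy),
        (cv_limit, band), bool(passed), scope,
    )


def inter_day_battery(
    day_tables: Sequence[tuple[object, Sequence[float]]],
    nominal: float,
    is_lloq: bool = False,
) -> QCBatteryResult:
    """Inter-day precision/accuracy: pool every replicate across days."""
    if len(day_tables) < 2:
        raise ValueError("inter-day study requires at least 2 days")
    pooled = [v for _, vals in day_tables for v in vals]
    return precision_accuracy(pooled, nominal, is_lloq, scope="inter_day")


def assess_matrix_effect(
    lot_results: Mapping[object, float], nominal: float
) -> QCBatteryResult:
    """Matrix-effect battery across plasma lots spiked at the LLOQ.

    One measured value per lot, at least six independent lots (design
    requirement); LLOQ limits apply.
    """
    if len(lot_results) < 6:
        raise ValueError("matrix-effect assessment requires >= 6 plasma lots")
    return precision_accuracy(
        list(lot_results.values()), nominal, is_lloq=True, scope="matrix_effect"
    )


def assess_selectivity(blank_peak_area: float, lloq_peak_area: float) -> bool:
    """True iff the blank-matrix signal is less than 20% of the LLOQ signal."""
    if lloq_peak_area <= 0:
        raise ValueError("LLOQ peak area must be positive")
    return blank_peak_area < 0.20 * lloq_peak_area


def qualify_lloq(candidate_result: QCBatteryResult) -> bool:
    """Does a candidate lowest level meet the LLOQ precision/accuracy limits?"""
    cv_ok = candidate_result.cv_pct <= CV_LIMIT_LLOQ_PCT * (1 + _EPS)
    lo, hi = ACCURACY_BAND_LLOQ
    acc_ok = lo * (1 - _EPS) <= candidate_result.accuracy_pct <= hi * (1 + _EPS)
    return bool(cv_ok and acc_ok)


def assess_stability(stored: Sequence[float], nominal: float) -> QCBatteryResult:
    """Accuracy of QCs after storage (triplicate minimum, non-LLOQ limits)."""
    if len(stored) < 3:
        raise ValueError("stability assessment requires triplicates")
    return precision_accuracy(stored, nominal, is_lloq=False, scope="stability")


def stage_recovery(
    areas_before: Sequence[float],
    areas_after: Sequence[float],
    *,
    peptide_id: str = "",
    stage: str = "",
) -> RecoveryResult:
    """Recovery of one preparation stage from paired peak-area ratios.

    recovery% = mean(after)/mean(before) × 100; the CV comes from the
    replicate-wise after/before ratios.
    """
    before = np.asarray(list(areas_before), dtype=float)
    after = np.asarray(list(areas_after), dtype=float)
    if before.size != after.size:
        raise ValueError("before/after must be paired")
    if before.size < 3:
        raise ValueError("recovery requires at least 3 paired replicates")
    if np.mean(before) == 0:
        raise ValueError("zero mean before-area")
    recovery = float(np.mean(after) / np.mean(before) * 100.0)
    ratios = after / before
    cv = float(np.std(ratios, ddof=1) / np.mean(ratios) * 100.0) if np.mean(ratios) else math.inf
    return RecoveryResult(peptide_id, stage, recovery, cv)


def total_recovery(stages: Sequence[RecoveryResult]) -> RecoveryResult:
    """Overall recovery: product of the digestion, SPE and ionization fractions.

    The CV is propagated to first order as the quadrature sum of the stage
    CVs (stages treated as independent).
    """
    required = {"digestion", "spe", "ionization"}
    by_stage = {r.stage: r for r in stages}
    missing = required - set(by_stage)
    if missing:
        raise ValueError(f"missing stage recoveries: {sorted(missing)}")
    frac = 1.0
    for name in required:
        frac *= by_stage[name].recovery_pct / 100.0
    cv = math.sqrt(sum(by_stage[name].cv_pct ** 2 for name in required))
    pid = next(iter(stages)).peptide_id
    return RecoveryResult(pid, "total", frac * 100.0, cv)


def assess_linearity(curves: Sequence) -> tuple[float, float]:
    """Mean and SD of the regression coefficient r² across validation runs."""
    if len(curves) < 2:
        raise ValueError("linearity summary requires at least 2 runs")
    r2 = np.array([c.r2 for c in curves], dtype=float)
    return float(np.mean(r2)), float(np.std(r2, ddof=1))
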