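"""Reference checks reproducing the assay's published figures of merit.

Each function here recomputes, from scratch through the package's public
surface, one quantity the validated assay reports: worked accuracy cells,
recovery accounting, cohort bookkeeping, exposure–response recovery on
synthetic cohorts, Fisher-exact oracle agreement, quantification round
trips, and weighting-selection behaviour.  ``scripts/acceptance.py`` and
the acceptance test suite both run these.
"""

from __future__ import annotations

import math

import numpy as np

from .assay import build_cetuximab_assay
from .quantify import fit_calibration, measure_peptide, quantify_sample
from .simulate import (
    CohortSimConfig,
    SimConfig,
    simulate_calibration_batch,
    simulate_cohort,
    simulate_qc_replicates,
    simulate_sample_chromatograms,
)
from .tdm import binormal_threshold, compare_groups_ttest, exact_association, roc_analysis
from .validation import RecoveryResult, precision_accuracy, total_recovery

SPIKE_CONCS = (5.0, 40.0, 150.0)  # µg/mL spiked samples for the round-trip check


def worked_accuracy_cells() -> dict[str, float]:
    """Accuracy = mean/nominal × 100 at the printed QC means."""
    cells = {
        "qc90_intraday": (79.7, 90.0),
        "qc175_intraday": (178.0, 175.0),
        "qc90_interday": (79.3, 90.0),
    }
    return {
        key: precision_accuracy([m, m], nom).accuracy_pct
        for key, (m, nom) in cells.items()
    }


def ht4_total_recovery_pct() -> float:
    """Product of the HT4 stage recoveries (89.5 / 48.1 / 50.8 %)."""
    stages = [
        RecoveryResult("HT4", "digestion", 89.5, 2.8),
        RecoveryResult("HT4", "spe", 48.1, 3.4),
        RecoveryResult("HT4", "ionization", 50.8, 8.1),
    ]
    return total_recovery(stages).recovery_pct


def cohort_shares() -> dict[str, float]:
    """Low-Cmin share (9/25) and progressive-disease share (10/25)."""
    return {
        "low_cmin_share_pct": 9 / 25 * 100.0,
        "progressive_share_pct": 10 / 25 * 100.0,
    }


def cohort_recovery(seed: int, n_cohorts: int = 200) -> dict[str, float]:
    """Threshold recovery and t-test power over synthetic pilot cohorts.

    Cohorts are drawn at the study's group distributions (15 benefit
    ~N(49.0, 16.3²), 10 progressive ~N(25.8, 17²), truncated ≥ 0).  The
    smoothed (binormal) Youden threshold is checked against the 25–45
    µg/mL band; the empirical-ROC cutpoint fraction is reported alongside.
    """
    rng = np.random.default_rng(seed)
    sub = rng.integers(0, 2**31 - 1, n_cohorts)
    thr_ok = emp_ok = p_ok = 0
    pooled = []
    for s in sub:
        cohort = simulate_cohort(CohortSimConfig(seed=int(s)))
        t, _, _ = binormal_threshold(cohort, "cmin")
        thr_ok += 25.0 <= t <= 45.0
        emp_ok += 25.0 <= roc_analysis(cohort, "cmin").threshold <= 45.0
        _, _, _, p = compare_groups_ttest(cohort, "cmin")
        p_ok += p < 0.05
        pooled.append(np.mean([r.cmin for r in cohort]))
    return {
        "youden_threshold_in_band_fraction": thr_ok / n_cohorts,
        "empirical_threshold_in_band_fraction": emp_ok / n_cohorts,
        "ttest_significant_fraction": p_ok / n_cohorts,
        "pooled_cmin_mean": float(np.mean(pooled)),
    }


def fisher_oracle_max_abs_diff(
    seed: int, exhaustive_total: int = 28, n_random: int = 600
) -> float:
    """Max |p_scipy − p_enumeration| over fixed-margin 2×2 tables.

    Exhaustive up to ``exhaustive_total``; random tables with totals up to
    60 on top; always includes [[5,0],[0,5]] and [[13,2],[3,7]].
    """

    def oracle(a, b, c, d):
        n, r, col = a + b + c + d, a + b, a + c
        lo, hi = max(0, r + col - n), min(r, col)
        probs = {
            k: math.comb(r, k) * math.comb(n - r, col - k)
            for k in range(lo, hi + 1)
        }
        pobs = probs[a]
        return sum(v for v in probs.values() if v <= pobs) / math.comb(n, col)

    tables = [(5, 0, 0, 5), (13, 2, 3, 7)]
    for n in range(2, exhaustive_total + 1):
        for a in range(n + 1):
            for b in range(n + 1 - a):
                for c in range(n + 1 - a - b):
                    d = n - a - b - c
                    if min(a + b, c + d, a + c, b + d) == 0:
                        continue
                    tables.append((a, b, c, d))
    rng = np.random.default_rng(seed)
    while n_random > 0:
        a, b, c, d = rng.integers(0, 31, 4)
        if a + b + c + d <= 60 and min(a + b, c + d, a + c, b + d) > 0:
            tables.append((int(a), int(b), int(c), int(d)))
            n_random -= 1
    worst = 0.0
    for a, b, c, d in tables:
        p = exact_association([[a, b], [c, d]]).p_value
        worst = max(worst, abs(p - oracle(a, b, c, d)))
    return worst


def _calibrate(assay, config, rng):
    man, chroms = simulate_calibration_batch(assay, None, config, rng=rng)
    curves = {}
    for pep in assay:
        levels = sorted(
            (float(row.nominal_conc),
             measure_peptide(chroms[row.sample_id], pep).response_ratio)
            for row in man.itertuples()
        )
        curves[pep.peptide_id] = fit_calibration(levels, peptide_id=pep.peptide_id)
    return curves


def noise_free_roundtrip() -> dict[str, float]:
    """Noise-free batch: back-calculation error of every standard, and r²."""
    assay = build_cetuximab_assay()
    cfg = SimConfig(seed=0, noise_cv=0.0, rt_jitter_sd=0.0)
    curves = _calibrate(assay, cfg, np.random.default_rng(0))
    worst = 0.0
    r2_min = 1.0
    for curve in curves.values():
        for (nominal, _), acc in zip(curve.levels, curve.back_calc_accuracy):
            worst = max(worst, abs(acc / 100.0 - 1.0))
        r2_min = min(r2_min, curve.r2)
    return {"max_rel_backcalc_error": worst, "min_r2": r2_min}


def noisy_roundtrip(seed: int, n_runs: int = 200) -> dict[str, float]:
    """Monte-Carlo batches at default noise (CV 5%).

    Per run: calibrate, quantify spiked samples at 5/40/150 µg/mL
    (consensus within 15% of truth?), and run the intra-day QC battery at
    1/1.8/90/175 µg/mL (all four levels within EMA limits?).
    """
    assay = build_cetuximab_assay()
    rng_master = np.random.default_rng(seed)
    sub = rng_master.integers(0, 2**31 - 1, n_runs)
    cons_ok = qc_ok = 0
    for s in sub:
        cfg = SimConfig(seed=int(s))
        rng = np.random.default_rng(int(s))
        curves = _calibrate(assay, cfg, rng)
        if not all(c.curve_valid for c in curves.values()):
            continue
        run_ok = True
        for conc in SPIKE_CONCS:
            chroms = simulate_sample_chromatograms(
                assay, conc, config=cfg, rng=rng, sample_id=f"SPK{conc:g}"
            )
            res = quantify_sample(
                measure_peptide(chroms, assay[0]),
                measure_peptide(chroms, assay[1]),
                curves,
            )
            if res.consensus_conc is None or abs(res.consensus_conc - conc) / conc > 0.15:
                run_ok = False
        cons_ok += run_ok
        man, chroms = simulate_qc_replicates(assay, None, 6, 1, cfg, rng=rng)
        lloq = float(man["nominal_conc"].min())
        level_ok = True
        for level, grp in man.groupby("nominal_conc"):
            vals = []
            for sid in grp["sample_id"]:
                res = quantify_sample(
                    measure_peptide(chroms[sid], assay[0]),
                    measure_peptide(chroms[sid], assay[1]),
                    curves,
                )
                vals.append(
                    res.consensus_conc
                    if res.consensus_conc is not None
                    else float(np.mean(list(res.conc_by_peptide.values())))
                )
            level_ok &= precision_accuracy(vals, float(level), level == lloq).passed
        qc_ok += level_ok
    return {
        "consensus_within_15pct_fraction": cons_ok / n_runs,
        "qc_battery_pass_fraction": qc_ok / n_runs,
    }


def weighting_selection(seed: int, n_runs: int = 200) -> dict[str, float]:
    """Weighting chosen on simulated batches under the two noise models."""
    assay = build_cetuximab_assay()
    rng_master = np.random.default_rng(seed)
    sub = rng_master.integers(0, 2**31 - 1, n_runs)
    out = {}
    for model, target in (("proportional", "1/x^2"), ("constant", "1")):
        hits = 0
        for s in sub:
            cfg = SimConfig(seed=int(s), noise_model=model)
            curves = _calibrate(assay, cfg, np.random.default_rng(int(s) ^ 0x5EED))
            hits += curves["HT4"].weighting == target
        key = ("weight_1x2_heteroscedastic_fraction" if model == "proportional"
               else "weight_unweighted_homoscedastic_fraction")
        out[key] = hits / n_runs
    return out
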