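"""End-to-end orchestration: chromatograms + manifest → run report.

Stages: per-peptide measurement of every sample, calibration on the
standards (with weighting selection and level acceptance), quantification
of QC and patient samples, the precision/accuracy battery when a QC
design is present, and the cohort exposure–response analysis when patient
outcomes are present.  Everything is deterministic given the inputs.
"""

from __future__ import annotations

import math
from typing import Mapping

import numpy as np
import pandas as pd

from . import tdm as tdm_mod
from .assay import PeptideAssay, build_cetuximab_assay, validate_assay
from .chromatogram import Chromatogram
from .quantify import (
    CalibrationCurve,
    PeptideMeasurement,
    SampleResult,
    fit_calibration,
    measure_peptide,
    quantify_sample,
)
from .validation import inter_day_battery, precision_accuracy

__all__ = ["PipelineError", "run_pipeline", "measured_concentration"]


class PipelineError(RuntimeError):
    pass


def _measurements_for(
    sample_id: str,
    chroms: Mapping[str, list[Chromatogram]],
    assay: list[PeptideAssay],
    window: float,
) -> dict[str, PeptideMeasurement]:
    if sample_id not in chroms:
        raise PipelineError(f"no chromatograms for sample {sample_id!r}")
    return {
        pep.peptide_id: measure_peptide(chroms[sample_id], pep, window=window)
        for pep in assay
    }


def measured_concentration(result: SampleResult) -> float | None:
    """Reported concentration of a sample under the BLQ→0 convention.

    Valid consensus when available; otherwise the mean of whatever
    per-peptide determinations exist (the flags travel with the result);
    0.0 when no analyte signal was found (below the quantification range).
    """
    if result.consensus_conc is not None:
        return result.consensus_conc
    if result.conc_by_peptide:
        return float(np.mean(list(result.conc_by_peptide.values())))
    return 0.0


def run_pipeline(
    manifest: pd.DataFrame,
    chroms: Mapping[str, list[Chromatogram]],
    assay: list[PeptideAssay] | None = None,
    *,
    window: float = 0.3,
    seed: int | None = None,
) -> dict:
    """Run every applicable stage and return a JSON-ready report."""
    assay = assay if assay is not None else build_cetuximab_assay()
    violations = validate_assay(assay)
    if violations:
        raise PipelineError(f"invalid assay definition: {violations}")

    report: dict = {"seed": seed, "n_samples": int(len(manifest))}

    measurements: dict[str, dict[str, PeptideMeasurement]] = {}
    for sid in manifest["sample_id"]:
        measurements[sid] = _measurements_for(sid, chroms, assay, window)

    # --- calibration on the standards
    standards = manifest[manifest["role"] == "standard"]
    if standards.empty:
        raise PipelineError("manifest contains no calibration standards")
    curves: dict[str, CalibrationCurve] = {}
    for pep in assay:
        levels = sorted(
            (float(row["nominal_conc"]),
             measurements[row["sample_id"]][pep.peptide_id].response_ratio)
            for _, row in standards.iterrows()
        )
        curves[pep.peptide_id] = fit_calibration(levels, peptide_id=pep.peptide_id)
    report["calibration"] = {
        pid: {
            "weighting": c.weighting,
            "slope": c.slope,
            "intercept": c.intercept,
            "r2": c.r2,
            "back_calc_accuracy_pct": c.back_calc_accuracy,
            "level_accepted": c.level_accepted,
            "curve_valid": c.curve_valid,
        }
        for pid, c in curves.items()
    }
    invalid = [pid for pid, c in curves.items() if not c.curve_valid]
    if invalid:
        raise PipelineError(
            f"calibration invalid for {invalid}; aborting sample quantification"
        )

    # --- quantify QC and patient samples
    results: dict[str, SampleResult] = {}
    for _, row in manifest[manifest["role"].isin(["qc", "patient"])].iterrows():
        sid = row["sample_id"]
        meas = measurements[sid]
        results[sid] = quantify_sample(meas["HT4"], meas["LT3"], curves)
    report["samples"] = {
        sid: {
            "conc_by_peptide": r.conc_by_peptide,
            "consensus_conc": r.consensus_conc,
            "concordance_pct": r.concordance_pct,
            "qc_flags": sorted(r.qc_flags),
            "valid": r.valid,
        }
        for sid, r in sorted(results.items())
    }

    # --- validation battery over the QC design
    qc = manifest[manifest["role"] == "qc"]
    if not qc.empty:
        battery = {}
        lloq = float(qc["nominal_conc"].min())
        for level, level_rows in qc.groupby("nominal_conc"):
            is_lloq = level == lloq
            by_day = {
                int(day): [
                    measured_concentration(results[sid])
                    for sid in day_rows["sample_id"]
                ]
                for day, day_rows in level_rows.groupby("day")
            }
            first_day = min(by_day)
            entry = {
                "intra_day": precision_accuracy(
                    by_day[first_day], float(level), is_lloq
                )
            }
            if len(by_day) > 1:
                entry["inter_day"] = inter_day_battery(
                    sorted(by_day.items()), float(level), is_lloq
                )
            battery[f"{float(level):g}"] = entry
        report["qc_battery"] = {
            lvl: {
                scope: {
                    "n": b.n,
                    "mean": b.mean,
                    "cv_pct": b.cv_pct,
                    "accuracy_pct": b.accuracy_pct,
                    "passed": b.passed,
                }
                for scope, b in entry.items()
            }
            for lvl, entry in battery.items()
        }

    # --- exposure–response analysis when outcomes are present
    patients = manifest[
        (manifest["role"] == "patient") & (manifest["outcome"].astype(str) != "")
    ]
    if patients.empty:
        report["tdm"] = {"skipped": "no patient samples with outcome labels"}
        return report

    per_patient: dict[str, dict] = {}
    for _, row in patients.iterrows():
        pid = str(row["patient_id"]) or str(row["sample_id"]).rsplit("_", 1)[0]
        rec = per_patient.setdefault(
            pid, {"outcome": str(row["outcome"]), "cmin": None, "cmax": None}
        )
        conc = measured_concentration(results[row["sample_id"]])
        rec[str(row["draw_type"])] = conc
    cohort = [
        tdm_mod.CohortRecord(pid, d["cmin"], d["cmax"], d["outcome"])
        for pid, d in sorted(per_patient.items())
        if d["cmin"] is not None and d["cmax"] is not None
    ]
    if len({r.outcome for r in cohort}) < 2:
        report["tdm"] = {"skipped": "only one outcome class present"}
        return report

    analysis: dict = {}
    for which in ("cmin", "cmax"):
        s = tdm_mod.summarize_exposure(cohort, which)
        ma, mb, t, p = tdm_mod.compare_groups_ttest(cohort, which)
        roc = tdm_mod.roc_analysis(cohort, which)
        table = tdm_mod.association_table(cohort, roc.threshold, which)
        try:
            exact = tdm_mod.exact_association(table)
            fisher = {
                "table": exact.table,
                "odds_ratio": exact.odds_ratio,
                "ci95": exact.ci95,
                "p": exact.p_value,
            }
        except ValueError as err:  # degenerate split (empty margin)
            fisher = {"table": table, "skipped": str(err)}
        analysis[which] = {
            "summary": s._asdict(),
            "ttest": {"mean_benefit": ma, "mean_progressive": mb, "t": t, "p": p},
            "roc": {
                "threshold": roc.threshold,
                "sensitivity_pct": roc.sensitivity_pct,
                "specificity_pct": roc.specificity_pct,
                "auc": roc.auc,
                "n_low": roc.n_low,
                "n_high": roc.n_high,
            },
            "fisher": fisher,
        }
    report["tdm"] = analysis
    return report
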