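"""Synthetic SRM data with the statistical structure the pipeline assumes.

The generator emulates the assay end to end at the chromatogram level:
Gaussian peaks on a flat baseline at each transition's expected retention
time (closed-form area A·σ·√(2π) makes integration testable), a scheduled
acquisition window around each peptide with ~15 points per peak, stage
recovery losses (digestion, SPE, ionization) applied to the light channel,
a deterministic internal-standard (heavy) response, per-transition
detector noise that is proportional (CV-constant) by default or
constant-variance on request, shared light/heavy retention-time jitter,
and day-level response drift for inter-day designs.

Cohorts are drawn from group-specific truncated normal distributions of
trough (Cmin) and peak (Cmax) plasma concentration: 15 clinical-benefit
patients around 49.0 ± 16.3 µg/mL Cmin and 10 progressive-disease patients
around 25.8 ± 17 µg/mL, with Cmax analogues.  Cmin and Cmax are drawn
independently per patient; no dosing-history PK model is simulated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assay import HEAVY, LIGHT, PeptideAssay
from .chromatogram import Chromatogram
from .tdm import CohortRecord

__all__ = [
    "SimConfig",
    "CohortSimConfig",
    "simulate_sample_chromatograms",
    "simulate_calibration_batch",
    "simulate_qc_replicates",
    "simulate_patient_samples",
    "simulate_cohort",
    "simulate_study",
    "DEFAULT_CALIBRATION_LEVELS",
    "DEFAULT_QC_LEVELS",
]

GAUSS_AREA = math.sqrt(2.0 * math.pi)

#: 9 standards spanning the validated 1–1000 µg/mL range (geometric spacing;
#: the individual levels are a generator default, only the span is fixed).
DEFAULT_CALIBRATION_LEVELS = tuple(np.geomspace(1.0, 1000.0, 9))
#: LLOQ, low, mid and high QC concentrations (µg/mL).
DEFAULT_QC_LEVELS = (1.0, 1.8, 90.0, 175.0)


def _default_recoveries():
    # Per-stage mean recovery fractions of the two peptides in plasma.
    return {
        "HT4": {"digestion": 0.895, "spe": 0.481, "ionization": 0.508},
        "LT3": {"digestion": 1.033, "spe": 0.636, "ionization": 0.479},
    }


def _default_response_factor():
    # Detector response (area units per µg/mL) before recovery losses.
    return {"HT4": 4000.0, "LT3": 4000.0}


def _default_qualifier_ratios():
    # Qualifier area as a fraction of the quantifier area, keyed by product m/z.
    return {
        "HT4": {851.6: 0.55, 759.0: 0.30},
        "LT3": {708.6: 0.62, 752.2: 0.35},
    }


@dataclass
class SimConfig:
    """Knobs of the chromatogram generator (units in field comments)."""

    seed: int = 0
    peak_sigma: float = 0.05  # min; chromatographic peak width
    sampling_interval: float = 0.005  # min; ~15 points across ±0.4σ·FWHM
    acquisition_window: float = 0.5  # min; scheduled-SRM half window
    response_factor: dict = field(default_factory=_default_response_factor)
    stage_recoveries: dict = field(default_factory=_default_recoveries)
    noise_cv: float = 0.05  # fractional amplitude noise per light transition
    noise_model: str = "proportional"  # or "constant"
    noise_ref_conc: float = 100.0  # µg/mL; sets the sd of "constant" noise
    baseline_level: float = 200.0  # counts
    trace_noise_scale: float = 2000.0  # counts; point noise sd = noise_cv * this
    rt_jitter_sd: float = 0.02  # min; shared by light and heavy per peptide
    interference_probability: float = 0.0
    day_effect_cv: float = 0.05  # light-channel response drift between days
    qualifier_ratios: dict = field(default_factory=_default_qualifier_ratios)

    def validate(self) -> None:
        if self.peak_sigma <= 0:
            raise ValueError("peak_sigma must be positive")
        if not (0 < self.sampling_interval < self.peak_sigma):
            raise ValueError("sampling_interval must be in (0, peak_sigma)")
        if self.noise_cv < 0 or self.rt_jitter_sd < 0:
            raise ValueError("noise_cv and rt_jitter_sd must be non-negative")
        if self.noise_model not in ("proportional", "constant"):
            raise ValueError(f"unknown noise_model {self.noise_model!r}")
        if not (0 <= self.interference_probability <= 1):
            raise ValueError("interference_probability must be in [0, 1]")
        for pep, stages in self.stage_recoveries.items():
            for stage, r in stages.items():
                if not (0 < r <= 1.2):
                    raise ValueError(f"recovery {pep}/{stage}={r} outside (0, 1.2]")

    def total_recovery(self, peptide_id: str) -> float:
        return float(np.prod(list(self.stage_recoveries[peptide_id].values())))


@dataclass
class CohortSimConfig:
    """Group-specific exposure distributions of the 25-patient pilot cohort."""

    n_benefit: int = 15
    n_progressive: int = 10
    cmin_benefit_mean: float = 49.0  # µg/mL
    cmin_benefit_sd: float = 16.3
    cmin_progressive_mean: float = 25.8
    cmin_progressive_sd: float = 17.0
    cmax_benefit_mean: float = 143.7
    cmax_benefit_sd: float = 37.9
    cmax_progressive_mean: float = 100.9
    cmax_progressive_sd: float = 24.6
    truncate_at_zero: bool = True
    toxicity_rate: float = 0.24  # 6 of 25 patients with grade-3 toxicity
    seed: int = 0

    def validate(self) -> None:
        if self.n_benefit < 1 or self.n_progressive < 1:
            raise ValueError("group counts must be >= 1")
        for name in ("cmin_benefit_sd", "cmin_progressive_sd",
                     "cmax_benefit_sd", "cmax_progressive_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def _gaussian(times, center, sigma, area):
    height = area / (sigma * GAUSS_AREA)
    return height * np.exp(-0.5 * ((times - center) / sigma) ** 2)


def _amp_noise(area, peptide_id, config, rng):
    if config.noise_cv == 0:
        return area
    if config.noise_model == "proportional":
        area = area * (1.0 + config.noise_cv * rng.standard_normal())
    else:  # constant variance on the area scale
        sd = (
            config.noise_cv
            * config.response_factor[peptide_id]
            * config.total_recovery(peptide_id)
            * config.noise_ref_conc
        )
        area = area + sd * rng.standard_normal()
    return max(area, 0.0)


def simulate_sample_chromatograms(
    assay: list[PeptideAssay],
    true_conc: float,
    sil_amount: float = 50_000.0,
    config: SimConfig | None = None,
    *,
    sample_id: str = "sample",
    rng: np.random.Generator | None = None,
    day_factors: dict | None = None,
) -> list[Chromatogram]:
    """One sample's traces: one Chromatogram per transition (12 by default).

    The light quantifier carries area ``true_conc × response_factor ×
    ∏(stage recoveries)`` (times the day factor and amplitude noise); the
    heavy quantifier carries ``sil_amount`` independent of concentration;
    qualifiers are fixed fractions of their quantifier.  Light and heavy
    share one jittered retention time per peptide.
    """
    config = config or SimConfig()
    config.validate()
    if true_conc < 0:
        raise ValueError("true_conc must be >= 0")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    day_factors = day_factors or {}

    traces: list[Chromatogram] = []
    for pep in assay:
        rec = config.total_recovery(pep.peptide_id)
        rf = config.response_factor[pep.peptide_id]
        rt0 = pep.transitions[0].expected_rt
        rt = rt0 + (config.rt_jitter_sd * rng.standard_normal()
                    if config.rt_jitter_sd > 0 else 0.0)
        day_f = day_factors.get(pep.peptide_id, 1.0)
        base_light = true_conc * rf * rec * day_f
        # qualifier fractions are keyed by light product m/z; the heavy
        # qualifier at the same position shares its light partner's fraction
        fracs = config.qualifier_ratios[pep.peptide_id]
        frac_by_key = {}
        light_quals = [t for t in pep.transitions
                       if t.channel == LIGHT and not t.is_quantifier]
        heavy_quals = [t for t in pep.transitions
                       if t.channel == HEAVY and not t.is_quantifier]
        for lt, ht in zip(light_quals, heavy_quals):
            frac_by_key[(LIGHT, lt.product_mz)] = fracs[lt.product_mz]
            frac_by_key[(HEAVY, ht.product_mz)] = fracs[lt.product_mz]

        interfere = (
            config.interference_probability > 0
            and rng.random() < config.interference_probability
        )
        times = np.arange(
            rt0 - config.acquisition_window,
            rt0 + config.acquisition_window + 0.5 * config.sampling_interval,
            config.sampling_interval,
        )
        for tdef in pep.transitions:
            frac = 1.0 if tdef.is_quantifier else frac_by_key[(tdef.channel, tdef.product_mz)]
            if tdef.channel == LIGHT:
                area = _amp_noise(base_light * frac, pep.peptide_id, config, rng)
            else:
                area = sil_amount * frac
            signal = np.full_like(times, config.baseline_level)
            if area > 0:
                signal = signal + _gaussian(times, rt, config.peak_sigma, area)
            if interfere and tdef.channel == LIGHT:
                # co-extracted interfering component, offset from the analyte
                signal = signal + _gaussian(
                    times, rt0 + 0.25, config.peak_sigma,
                    rng.uniform(0.2, 1.0) * max(base_light, rf * rec),
                )
            if config.noise_cv > 0 and config.trace_noise_scale > 0:
                signal = signal + (
                    config.noise_cv * config.trace_noise_scale
                    * rng.standard_normal(times.size)
                )
            traces.append(
                Chromatogram(sample_id, tdef, times, np.maximum(signal, 0.0))
            )
    return traces


def _manifest_row(sample_id, role, nominal=np.nan, day=1, draw_type="",
                  outcome="", patient_id=""):
    return {
        "sample_id": sample_id,
        "role": role,
        "nominal_conc": nominal,
        "day": day,
        "draw_type": draw_type,
        "outcome": outcome,
        "patient_id": patient_id,
    }


def simulate_calibration_batch(
    assay: list[PeptideAssay],
    levels=None,
    config: SimConfig | None = None,
    *,
    sil_amount: float = 50_000.0,
    rng: np.random.Generator | None = None,
    day: int = 1,
    id_prefix: str = "STD",
):
    """Calibration standards: manifest + chromatograms, default 9 levels 1–1000."""
    config = config or SimConfig()
    levels = DEFAULT_CALIBRATION_LEVELS if levels is None else tuple(levels)
    if len(levels) < 2:
        raise ValueError("need at least 2 calibration levels")
    if any(l <= 0 for l in levels) or any(
        b <= a for a, b in zip(levels, levels[1:])
    ):
        raise ValueError("levels must be positive and strictly increasing")
    rng = rng if rng is not None else np.random.default_rng(config.seed)

    rows, chroms = [], {}
    for i, level in enumerate(levels, start=1):
        sid = f"{id_prefix}{i:02d}"
        rows.append(_manifest_row(sid, "standard", nominal=level, day=day))
        chroms[sid] = simulate_sample_chromatograms(
            assay, level, sil_amount, config, sample_id=sid, rng=rng
        )
    return pd.DataFrame(rows), chroms


def simulate_qc_replicates(
    assay: list[PeptideAssay],
    qc_levels=None,
    n_reps: int = 6,
    n_days: int = 3,
    config: SimConfig | None = None,
    *,
    sil_amount: float = 50_000.0,
    rng: np.random.Generator | None = None,
):
    """QC design: default 4 levels × 6 replicates × 3 days (72 samples).

    With more than one day, a day-level multiplicative drift (sd
    ``day_effect_cv``) is applied to the light-channel response of each
    peptide, so inter-day scatter exceeds intra-day scatter.
    """
    config = config or SimConfig()
    qc_levels = DEFAULT_QC_LEVELS if qc_levels is None else tuple(qc_levels)
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    rng = rng if rng is not None else np.random.default_rng(config.seed)

    rows, chroms = [], {}
    for day in range(1, n_days + 1):
        if n_days > 1 and config.day_effect_cv > 0:
            day_factors = {
                pep.peptide_id: 1.0 + config.day_effect_cv * rng.standard_normal()
                for pep in assay
            }
        else:
            day_factors = {}
        for level in qc_levels:
            for rep in range(1, n_reps + 1):
                sid = f"QC{level:g}_D{day}_R{rep}"
                rows.append(_manifest_row(sid, "qc", nominal=level, day=day))
                chroms[sid] = simulate_sample_chromatograms(
                    assay, level, sil_amount, config,
                    sample_id=sid, rng=rng, day_factors=day_factors,
                )
    return pd.DataFrame(rows), chroms


def _truncated_normal(rng, mean, sd, size, truncate):
    if sd == 0:
        return np.full(size, float(mean))
    vals = rng.normal(mean, sd, size)
    if truncate:
        while True:  # resample negatives; keeps the distribution conditional on >= 0
            bad = vals < 0
            if not bad.any():
                break
            vals[bad] = rng.normal(mean, sd, int(bad.sum()))
    return vals


def simulate_cohort(config: CohortSimConfig | None = None) -> list[CohortRecord]:
    """Draw a patient cohort with group-specific Cmin/Cmax distributions."""
    config = config or CohortSimConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    records: list[CohortRecord] = []
    groups = [
        ("clinical_benefit", config.n_benefit,
         config.cmin_benefit_mean, config.cmin_benefit_sd,
         config.cmax_benefit_mean, config.cmax_benefit_sd),
        ("progressive_disease", config.n_progressive,
         config.cmin_progressive_mean, config.cmin_progressive_sd,
         config.cmax_progressive_mean, config.cmax_progressive_sd),
    ]
    i = 0
    for outcome, n, mmin, smin, mmax, smax in groups:
        cmins = _truncated_normal(rng, mmin, smin, n, config.truncate_at_zero)
        cmaxs = _truncated_normal(rng, mmax, smax, n, config.truncate_at_zero)
        tox = rng.random(n) < config.toxicity_rate
        for j in range(n):
            i += 1
            records.append(
                CohortRecord(
                    patient_id=f"PT{i:02d}",
                    cmin=float(cmins[j]),
                    cmax=float(cmaxs[j]),
                    outcome=outcome,
                    severe_toxicity=bool(tox[j]),
                )
            )
    return records


def simulate_patient_samples(
    assay: list[PeptideAssay],
    cohort: list[CohortRecord],
    config: SimConfig | None = None,
    *,
    sil_amount: float = 50_000.0,
    rng: np.random.Generator | None = None,
):
    """Two draws (trough and peak) per patient at the cohort's true exposures."""
    config = config or SimConfig()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    rows, chroms = [], {}
    for rec in cohort:
        for draw, conc in (("cmin", rec.cmin), ("cmax", rec.cmax)):
            sid = f"{rec.patient_id}_{draw.upper()}"
            rows.append(
                _manifest_row(sid, "patient", draw_type=draw,
                              outcome=rec.outcome, patient_id=rec.patient_id)
            )
            chroms[sid] = simulate_sample_chromatograms(
                assay, conc, sil_amount, config, sample_id=sid, rng=rng
            )
    return pd.DataFrame(rows), chroms


def simulate_study(
    assay: list[PeptideAssay],
    config: SimConfig | None = None,
    cohort_config: CohortSimConfig | None = None,
    *,
    n_qc_days: int = 3,
    sil_amount: float = 50_000.0,
):
    """Full study batch: standards + QC design + patient samples + cohort table."""
    config = config or SimConfig()
    cohort_config = cohort_config or CohortSimConfig(seed=config.seed)
    rng = np.random.default_rng(config.seed)
    man_std, ch_std = simulate_calibration_batch(
        assay, None, config, sil_amount=sil_amount, rng=rng
    )
    man_qc, ch_qc = simulate_qc_replicates(
        assay, None, 6, n_qc_days, config, sil_amount=sil_amount, rng=rng
    )
    cohort = simulate_cohort(cohort_config)
    man_pt, ch_pt = simulate_patient_samples(
        assay, cohort, config, sil_amount=sil_amount, rng=rng
    )
    manifest = pd.concat([man_std, man_qc, man_pt], ignore_index=True)
    chroms = {**ch_std, **ch_qc, **ch_pt}
    return manifest, chroms, cohort
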