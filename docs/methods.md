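# Methods

## Scope and model

`srmtdm` implements the computational side of a stable-isotope-dilution
LC-MS/MS assay for cetuximab in human plasma and the downstream
therapeutic-drug-monitoring (TDM) analysis. The protein is quantified
through two proteotypic surrogate peptides from the CDR-containing
variable regions — HT4 (heavy chain, `GLEWLGVIWSGGNTDYNTPFTSR`) and LT3
(light chain, `ASQSIGTNIHWYQQR`) — each monitored by three SRM
transitions in a light (analyte) and a heavy ([13C6;15N4]-labelled
internal standard, "SIL") channel. The measurement unit is the response
ratio, light quantifier peak area over heavy quantifier peak area, which
cancels preparation recovery and ionization variation because the SIL
peptides are spiked before digestion.

The assay dictionary (precursor/product m/z, charge, collision energy,
expected retention time, quantifier flag) is fixed data, shipped as
`data/cetuximab_assay.yaml`; nothing is predicted from sequence.

## Peak processing

Scheduled SRM traces are short time/intensity series around each
peptide's expected retention time. Apex picking runs on a 5-point moving
average (at ~15 acquisition points per peak a raw argmax is
noise-sensitive); plateau ties resolve to the earliest time. Peak
boundaries sit where the smoothed trace falls to 5% of the apex height
above the local background, or at the search-window edge. A peak counts
as *found* when its apex rises at least 3× the background noise — a
conventional detection floor deliberately below the quantification limit,
which the LLOQ rules enforce later. Noise is 1.4826 × the median absolute
deviation of off-peak intensities (robust to stray spikes).

Integration is trapezoidal between the boundaries after subtracting a
straight baseline at the robust off-peak background level (median of the
trace outside the peak region, padded by one peak width). Anchoring the
baseline at the background level rather than at the boundary *trace*
intensities matters: with 5%-of-apex bounds, boundary-intensity anchoring
would clip ≈10% of a Gaussian peak's area, while background anchoring
loses only the ≈1.4% tail mass outside ±2.45σ. Because light and heavy
traces of a peptide share the peak shape, grid and boundary indices,
integration errors cancel exactly in the response ratio — on noise-free
input the measured ratio equals the configured one to machine precision.

## Quantification protocol

Two specificity gates precede quantification, both boundary-inclusive
(one convention applied to every rule in the package: "within 0.1 min",
"±25%", "±15/20%", "below 20%" all admit values exactly at the limit):

1. co-elution — light and heavy apexes within 0.1 min;
2. ion ratios — each qualifier/quantifier area ratio on the light channel
   within ±25% of its heavy-channel counterpart.

Calibration regresses response ratio on nominal concentration (9 levels,
1–1000 µg/mL) by weighted least squares with candidate weights 1, 1/x,
1/x². The weighting is selected by comparing the Gaussian profile
likelihood of the three variance models Var(yᵢ) = σ²/wᵢ, i.e. minimizing
n·log(SSR_w/n) − Σ log wᵢ. This is the consistent analogue of "pick the
weighting with the smallest residual sum" once residual scales differ
between weights: a naive sum of squared *relative* back-calculation
errors is (up to the slope factor) exactly the 1/x²-weighted SSR, so it
selects 1/x² regardless of the data; the likelihood criterion instead
tracks the true variance structure (measured on simulated batches: 1/x²
chosen in ~95% of CV-constant runs, the unweighted fit in ~88% of
constant-variance runs). Ties — e.g. exact data, where every weighting
fits perfectly — resolve to the simplest scheme (1, then 1/x, then 1/x²).

Standards must back-calculate to 85–115% of nominal (80–120% at the
lowest standard). A curve is valid when ≥ 75% of levels and ≥ 6 levels
pass and the slope is positive — the acceptance rule of the European
bioanalytical validation guideline this battery follows. Concentrations
above the top standard are flagged (`above_uloq`), never extrapolated;
dilution re-assay is out of scope.

A sample's concentration is the arithmetic mean of the HT4 and LT3
determinations, reported only when both gates pass and the two values
agree within 20% of their mean (the denominator choice is this package's;
maximum or single-peptide denominators would be alternatives). The
concordance metric is symmetric in the two peptides.

## Validation battery

Precision is CV = SD/mean × 100 with the sample (n−1) standard deviation;
accuracy is mean/nominal × 100. Default limits: CV ≤ 15%, accuracy
85–115%; at the LLOQ: CV ≤ 20%, accuracy 80–120%. Inter-day statistics
pool all replicates across days (rather than averaging day means), which
matches the inter-day n of the design (4 levels × 6 replicates × 3 days).
Matrix effect applies the LLOQ battery across ≥ 6 independent plasma
lots. Selectivity requires blank-matrix signal strictly below 20% of the
LLOQ response. Stage recoveries (digestion, SPE, ionization) are
after/before mean area-ratio quotients; the total recovery is the product
of the stage fractions, with a first-order (quadrature) CV propagation
that assumes independent stages.

## Exposure–response analysis

Cohort records carry trough (Cmin) and end-of-infusion (Cmax) plasma
concentrations and a binary outcome (clinical benefit vs progressive
disease). Group comparison uses the two-sided pooled-variance Student
t-test ("standard t-test"; Welch available as an option). The ROC treats
exposure ≥ threshold as predicting benefit; `roc_analysis` is fully
empirical (all observed exposures as cut-points, trapezoidal AUC, Youden
J maximized, ties toward the lower threshold). On tie-free data its AUC
equals the Mann–Whitney U statistic divided by n₁·n₂.

The empirical Youden cutpoint is highly variable on a 25-patient cohort —
it can only sit on observed values, and its sampling distribution has
heavy upper tails (95th percentile ≈ 52 µg/mL at the default cohort
parameters). `binormal_threshold` therefore offers a smoothed-ROC
operating point: each group is modelled as normal with its sample mean
and SD and J is maximized over continuous thresholds. This estimator
concentrates near the density crossover (~37 µg/mL for the default
groups) and yields non-integer sensitivity/specificity percentages, which
is also the only way a specificity that is not a multiple of 10% can
arise from 10 progressive patients. The parameter-recovery acceptance
check uses the binormal operating point; the empirical fraction is
reported alongside.

The 2×2 association (high/low exposure × outcome) uses Fisher's exact
test: two-sided p by summing fixed-margin table probabilities no larger
than the observed one, odds ratio as the conditional maximum-likelihood
estimate with its exact test-inversion 95% CI (the convention of standard
exact-test software). scipy provides the implementation; the test suite
checks it against an independent exhaustive integer-arithmetic
enumeration (p to 1e-10) and a direct noncentral-hypergeometric
likelihood maximization for the odds ratio.

## Synthetic data

The generator emulates the study's inputs so the pipeline is fully
testable offline:

- **Chromatograms** — Gaussian peaks (σ = 0.05 min) on a flat baseline
  (200 counts), sampled every 0.005 min in a ±0.5 min scheduled window;
  closed-form area A·σ·√(2π) makes integration testable. Light and heavy
  channels of a peptide share one jittered retention time per sample
  (SD 0.02 min).
- **Response model** — light quantifier area = concentration × response
  factor (4000 area units per µg/mL) × the product of stage recoveries
  (HT4 0.895·0.481·0.508, LT3 1.033·0.636·0.479 — the validated assay's
  digestion/SPE/ionization means); heavy area is the fixed SIL amount
  (50 000 area units), independent of concentration. Qualifier areas are
  fixed fractions of the quantifier (HT4 0.55/0.30, LT3 0.62/0.35 —
  plausible fragment-intensity ratios, a generator choice).
- **Noise** — per-transition light-channel amplitude noise, proportional
  (CV-constant, default CV 5%) or constant-variance (sd equal to the
  proportional noise at 100 µg/mL) to exercise weighting selection; the
  5% default reproduces intra-day concentration CVs in the 2–10% range of
  the validated assay. Additive trace noise (sd = CV × 2000 counts)
  gives finite S/N; with CV = 0 every output is exact. Carrying the
  amplitude noise on the light channel only reflects that the
  deterministic SIL amount is the reference the ratio is measured
  against. Day-level response drift (CV 5%, light channel) makes
  inter-day scatter exceed intra-day scatter in multi-day designs.
- **Designs** — 9 geometrically spaced standards over 1–1000 µg/mL (only
  the span and count are fixed by the method; the individual levels are a
  generator default), QCs at 1/1.8/90/175 µg/mL × 6 replicates × 3 days.
- **Cohort** — 15 clinical-benefit patients with Cmin ~ N(49.0, 16.3²)
  and Cmax ~ N(143.7, 37.9²), 10 progressive-disease patients with
  Cmin ~ N(25.8, 17²) and Cmax ~ N(100.9, 24.6²), truncated at zero by
  resampling; grade-3 toxicity assigned independently at rate 0.24.
  Cmin and Cmax are drawn independently per patient — no dosing-history
  PK model — because the analysis uses them marginally.

What the generator does *not* emulate: peak tailing/fronting, retention
drift across runs, co-eluting interferences by default
(`interference_probability` exists but defaults to 0), correlated
within-patient PK, carry-over, or degradation terms. Passing tests
therefore demonstrate the correctness of the computational pipeline under
the stated statistical structure, not robustness to every real-data
pathology.

## Problem sizes and numerical choices

Monte-Carlo acceptance checks use 200 replicates per condition (cohorts,
calibration batches, weighting runs), which bounds the sampling error of
a 90–95% pass fraction at roughly ±2–4 percentage points. The
Fisher-exact oracle comparison enumerates every valid-margin 2×2 table
with total ≤ 28 exhaustively plus 600 random tables with totals up to 60
(the agreement is at the 1e-15 level, so coverage, not tolerance, is the
limiting factor). Boundary comparisons use a relative slack of 1e-9 so
that values exactly at a limit pass regardless of floating-point
representation. Seeds derive from a single master seed via a PCG64
generator; identical seeds give bit-identical outputs.

## Known limitations

- The fixed 2×2 layout and dual-peptide consensus are specific to this
  two-peptide assay; generalizing to other proteins means supplying a new
  assay YAML and qualifier-ratio template.
- The empirical ROC reports the cutpoint as an observed exposure value;
  on small cohorts prefer the binormal operating point and treat the
  empirical one as descriptive.
- Total-recovery CV propagation assumes independent stages; correlated
  stage losses would need replicate-level bookkeeping.
- The mzML reader covers SRM chromatogram lists (32/64-bit float arrays,
  zlib or uncompressed); spectrum data and vendor extensions are not
  parsed.
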