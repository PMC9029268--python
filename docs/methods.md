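# Methods

## Scope and model

The package implements lesion-level metabolic response assessment for
two-timepoint FDG-PET studies. Its unit of analysis is the patient: per
scan, every index lesion carries SUVmax, SUVmean, SUVpeak, SULpeak, MTV,
TLG and a longest diameter; a per-scan liver reference (mean and SD over
a 3-cm sphere) anchors both the measurability floor and the
complete-response comparison. Classification applies four rule sets —
PERCIST 1.0 (SULpeak), mPERCIST (SUVpeak), PERCISTmax (SUVmax) and EORTC
(SUVmax) — and the DC/PD dichotomy feeds a survival comparison.

## Quantification choices

* **SUV.** SUV = c / (injected activity / body weight), density 1 g/mL.
* **SUL normalizer.** The literature is inconsistent about whether
  "SULpeak" is normalized by lean body mass or a body-surface-area
  surrogate, and rarely states the formula. Default: Janmahasatian LBM
  (sex- and BMI-specific); options: James LBM and Du Bois BSA mapped to
  a mass equivalent by standard-person scaling (70 kg per 1.73 m²,
  a convention of this package since BSA has no canonical kg scale).
  The method is a config flag recorded in run manifests; none is claimed
  to reproduce any particular clinical workstation.
* **SUVpeak geometry.** 12-mm-diameter sphere (~1 cm³), candidate
  centers restricted to voxel centers inside the lesion mask, sphere
  allowed to extend beyond the mask, voxel-in-sphere decided by voxel
  *center* within the radius (no partial-volume weighting). Implemented
  as a sum/count convolution; an exhaustive brute-force oracle in the
  test suite checks exact equivalence on random volumes.
* **MTV.** Clinical delineation is interactive; here a reproducible
  default: threshold at 42 % of lesion SUVmax (optional absolute floor),
  keep 26-connected components touching the seed. MTV is monotone
  non-increasing in the threshold (property-tested).
* **Liver reference.** Population SD (divisor n), so the "mean + 2 SD"
  floor is exactly reproducible; the sphere must lie fully inside the
  grid or the call errors.
* **Longest diameter.** Max pairwise distance between voxel centers;
  convex-hull acceleration above 300 voxels, with brute-force agreement
  tested (the diameter of a finite set is attained on its hull).

## Screening rules

Boundary inclusivity follows the wording of the published rules: "at
least 1.5 times" → measurable iff SULpeak ≥ 1.5 × (SULmean + 2 SD);
"exceeded 20 %" → a drift of exactly 20 % is still comparable. The 20 %
liver rule applies to all three PERCIST variants (via liver SULmean for
the SUL/SUVpeak variants, liver SUVmean for PERCISTmax; configurable)
and never to EORTC, which therefore classifies a superset of patients.
Measurability is assessed at baseline on each criteria set's own metric;
the SUVmax-based sets only require a lesion with positive uptake.
Non-comparability dominates non-availability in the reported status.

## Classification engine

One engine serves both families, parameterized by a `CriteriaSpec`
(metric, percent thresholds, absolute floors, size rule and its
strictness). Decisions of note:

* **Precedence** PMD > CMR > PMR > SMD; new lesions are unconditional
  progression.
* **Absolute 0.8 gate.** The progression conjunction (≥ +30 % *and*
  ≥ +0.8) is applied by all three PERCIST variants in their own metric
  units; the 0.8 *decrease* floor for PMR is enforced only for
  PERCIST 1.0, because it is stated in SUL units.
* **CMR operationalization.** Complete response hinges on the
  reader-level judgment "uptake indistinguishable from surrounding
  normal tissue", which a single liver threshold cannot stand in for (a
  deep partial responder may legitimately fall below liver SULmean).
  The lesion schema therefore carries a per-lesion boolean `resolved`;
  CMR requires every lesion resolved and, for the PERCIST family, every
  follow-up metric value at or below the liver reference level (EORTC's
  background level is liver mean + 2 SD as a normal-tissue proxy). In
  voxel mode `resolved` is derived as lesion SUVmax ≤ background mean +
  2 SD of unlabelled voxels; in table mode the generator sets it.
* **Target selection.** PERCIST hottest compares the hottest lesion of
  each scan independently; EORTC tracks the baseline-hottest lesion.
  The "all lesions" mode takes one index lesion per compartment (the
  baseline-hottest) and compares the *sum* of the metric — the common
  multi-lesion extension; a worst-lesion combiner was considered and
  rejected as it collapses onto the hottest mode for dominant lesions.
  Hotness ties break by larger MTV, then lexicographic lesion ID.
* **Size input.** PERCIST's target-lesion size is the target's MTV
  change (≥ +30 %, inclusive); EORTC's extent rule is the longest
  diameter of the tracked lesion (> +20 %, strict), taken from the MTV
  delineation rather than CT.

## Synthetic cohort

The table generator emulates the study conditions the analysis assumes:
25 patients by default, profile mix 8 % complete / 44 % partial
responders / 16 % stable / 32 % progressors (largest-remainder
allocation, so counts are exact), uptake changes drawn per patient from
normals with defaults −46 ± 25 % (responders) and +92 ± 34 %
(progressors), MTV changes −52 ± 31 % / +38 ± 94 %, 8 % of patients
with all lesions below the measurability floor, 12 % with liver drift
of 25–45 %, 1–4 lesions per patient in distinct compartments, exposure
4 MBq/kg.

Draws are deliberately **untruncated** (clipped only at the physical
−99 % bound; the stable profile at ±24 % so it stays inside every
criterion's stability band): truncating to class-consistent regions
would bias the group means away from the configured values and break
law-of-large-numbers recovery. Consequently the assigned profile is
recoverable by the pipeline with certainty only when the effect-size SDs
are set to zero ("zero-noise" configs), which is how exact truth
recovery is tested; with nonzero SDs a borderline draw may legitimately
cross a rule boundary. Baseline peak values of non-flagged patients are
floored at 1.05 × the measurability threshold so that eligibility
exclusions equal the injected flags exactly.

Survival times are exponential per group (defaults: medians 35.6 months
DC, 24.9 months PD, i.e. hazards ln 2 / median per month); censoring is
an independent exponential calibrated so the expected censored fraction
equals `censor_rate` (default 0.3). The voxel phantom paints spheres on
a 40³ grid at 4-mm spacing with multiplicative Gaussian noise (default
5 % of local level); follow-up lesion levels are baseline × (1 + Δ/100),
floored at background. The phantoms emulate contrast and geometry only —
no scanner physics, reconstruction artifacts, motion, or partial-volume
blur — so passing tests demonstrate correctness of the measurement and
decision logic, not robustness to real acquisition variability.

## Statistics

* **Kaplan–Meier** via lifelines; median = smallest t with S(t) ≤ 0.5,
  "not reached" when the curve never gets there.
* **Randomization log-rank.** Statistic (O − E)² / V with
  hypergeometric variance and tie handling; reference distribution from
  random relabelings of group membership with (time, event) pairs kept
  intact; p = (1 + #{permuted ≥ observed}) / (1 + n_perm) (add-one, so
  p > 0). The permutation loop is vectorized (suffix cumulative sums
  over a label matrix), which keeps 5000 permutations at n = 200 in
  milliseconds; the statistic is cross-checked against an independent
  library implementation in the tests.
* **Bootstrap t.** Shifted-null studentized variant: both samples
  centered to the pooled mean, resampled with replacement, Welch t
  recomputed; two-sided p doubles the smaller add-one tail (capped at
  1). Chosen over the percentile variant because it respects unequal
  variances; agreement with the classical Welch test on normal data is
  tested to 0.02.
* All stochastic operations take explicit seeds and are bit-reproducible.

## Problem sizes in the test suite

Rule-grid equivalence uses ~1.25 × 10⁵ input combinations; permutation
calibration uses 200 null replicates at n = 30/30 with 500 permutations
each plus a 100-replicate power check at n = 50/50 and hazard ratio 4;
truth recovery uses a 200-patient zero-noise cohort; effect-size
recovery 100 patients per group. These sizes give stable checks (3-SE
bands, KS at α = 0.01) while the whole suite runs in well under a
minute of CPU.

## Known limitations

* Lesion identity across scans is assumed given (stable IDs); no
  registration or automated matching.
* The EORTC "extent" diameter comes from PET delineation, not CT.
* The BSA mass-equivalent is a package convention, not a standard.
* No covariate adjustment (Cox) and no multiple-testing correction
  across criteria sets; p-values are reported unadjusted.
* Table mode trusts the input schema (validated structurally, not
  clinically); voxel mode assumes attenuation-corrected SUV-ready data.
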