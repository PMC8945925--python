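# Methods

This note records the models, conventions and design choices behind
`metpet`, and what the synthetic generators do and do not emulate.

## SUL quantification

Activity concentration volumes (MBq/g) are converted to SUL by scaling with
`LBM [g] / injected dose [MBq]`. The lean-body-mass estimator is not
standardized across PET workstations; we default to the Janmahasatian
formula (male `9270·W/(6680+216·BMI)`, female `9270·W/(8780+244·BMI)`),
which the PERCIST community recommends, and keep the older James formula
behind `LbmFormula.JAMES`. Decay correction is assumed already applied to
the input. Tests pass SUL volumes directly, so the LBM choice is isolated
from everything downstream.

Liver background is the mean and **sample** (n−1) standard deviation of SUL
over voxels whose centers fall inside a 3-cm-diameter sphere; the sphere
must lie fully inside the volume and, when a lesion-exclusion mask is
supplied, must not touch it (the caller re-sites the ROI, as a reader
would). Two thresholds follow:

- measurability gate `1.5·μ + 2·σ` — the wording "1.5-fold higher than the
  liver mean plus two standard deviations" is ambiguous; we read it the way
  PERCIST 1.0 prints it, with `1.5·(μ + 2σ)` available via `strict_parse`;
- VOI segmentation bound `μ + 2·σ`.

## Geometry conventions

World coordinates are mm. The center of voxel `(0,0,0)` sits at the volume
origin (NIfTI convention) and voxel `i` along an axis is centered at
`origin + i·spacing`. A voxel belongs to a sphere/ellipsoid iff its center
does; volume extents are half-open. These conventions are shared by the
phantom generator and the segmentation code, so voxelized ground-truth
volumes agree exactly with segmented MTVs on noiseless phantoms.

## Lesion analysis

Segmentation takes 26-connected components of `SUL ≥ μ + 2σ` (a standard
connectivity for blob-like PET uptake), optionally masking out
physiologic-uptake organ labels (brain, bladder, kidneys) — empty by
default because phantoms do not need it. A component is a measurable lesion
only if its SUL_max clears the measurability gate. Its organ is the
majority organ label of its voxels; MTV is `voxel count × voxel volume`;
TLG is `SUL_mean × MTV`, an identity that holds exactly by construction.

Ordering everywhere (hottest lesion, target selection) uses one tie-break
rule: descending SUL_max, then descending MTV, then ascending centroid in
lexicographic mm order. Target selection scans that order greedily,
skipping lesions whose organ already has two selected, and stops at five.
Against exhaustive enumeration this greedy set is the feasible subset whose
hotness sequence is lexicographically maximal.

Cross-timepoint matching emulates a reader re-identifying "the same
lesions": greedy nearest-centroid pairing, accepted only within 20 mm
(configurable) and with identical organ labels, assuming rigid alignment
between timepoints (no deformable registration). Unmatched follow-up
lesions are new-lesion candidates; unmatched baseline targets are treated
as resolved and contribute 0 to follow-up burden sums. Whether the original
analysis re-segmented follow-up lesions de novo or carried the baseline
five forward is not decidable from its description; we adopt
matched-lesions-only as the default interpretation.

## Response assessment

The PERCIST category derives from the hottest single lesion per scan — the
follow-up hottest need not be the baseline lesion. Precedence: PMD by new
lesion, then PMD by ΔSUL > +30%, then CMR (no measurable follow-up lesion),
then PMR (ΔSUL ≤ −30%), else SMD. Boundaries follow the inequality
directions exactly (−30% is PMR, +30% is SMD). The percentage-only rule set
is the default; strict PERCIST 1.0 additionally requires a 0.8-SUL-unit
absolute change for PMR/PMD and is available via `strict_percist`.
Responders (MR) are CMR ∪ PMR. Percentages are carried at full precision
in memory and rounded only at serialization (percents to 1 decimal, SUL to
2) — worked-case ΔSUL values can therefore differ in the last digit from
numbers printed by clinical workstations, which round earlier; categories
are unaffected.

## Outcome statistics

- Diagnostic metrics are plain ratios ×100; an empty denominator yields an
  undefined (None) metric, never 0.
- The odds ratio is the crude cross-product with a Woolf (log-normal) CI;
  zero cells require an explicit Haldane 0.5 correction.
- Mann–Whitney uses the exact null distribution when both groups have
  n ≤ 10 with no cross-group ties (the exact distribution assumes none),
  otherwise the tie-corrected normal approximation.
- The chi-square test switches to Fisher's exact test whenever an expected
  cell is below 5 — always the case at the n = 30 scale this pipeline
  targets.
- Kaplan–Meier, log-rank and Cox (partial likelihood, Efron ties, Wald CIs)
  are delegated to lifelines; the median CI is the band-crossing
  (Brookmeyer–Crowley-style) interval. Logistic models are delegated to
  statsmodels with explicit errors on separation. No multiple-testing
  correction is applied anywhere, mirroring the analysis style this
  pipeline reproduces; treat small p values across many candidate
  predictors accordingly.
- The optimal cutoff search evaluates log-rank p at every distinct observed
  value, visiting candidates from the sample median outward (alternating
  above/below) and keeping the minimum-p candidate whose two groups each
  hold ≥ 15% of the cohort (configurable floor; it exists to prevent
  1-patient groups at n = 30). Because every eligible candidate is visited,
  the result equals exhaustive minimization; the visiting order only
  resolves ties toward the median. The search trace is retained for audit.
  Maximally selected statistics inflate type-I error; the cutoff is
  descriptive, not a calibrated test.

## Synthetic phantoms

Phantoms are uniform-background grids with ellipsoidal lesions and a
spherical liver region whose voxels are drawn i.i.d. from N(mean, SD).
Lesions default to a uniform plateau at the peak SUL — chosen so SUL_mean,
MTV and TLG are analytically checkable — with a Gaussian-falloff profile
available. Global noise is additive Gaussian truncated at 0, keeping SUL
non-negative. Follow-up phantoms scale each lesion's peak by a
non-negative response factor (0 = complete resolution) and may add new
lesions; seeds make everything bit-reproducible.

Not emulated: scanner physics (PSF, scatter, attenuation), partial-volume
effects, respiratory motion, heterogeneous tumor texture, and anatomical
realism. Passing tests on phantoms therefore validate the *bookkeeping* —
thresholds, connectivity, selection, matching, arithmetic — not robustness
to real-image degradations.

## Simulated cohorts

Cohorts emulate a ~30-patient EGFR-mutant lung-adenocarcinoma population on
first-line EGFR-TKIs:

- `dct` (delta cycle threshold, cycles; lower = more mutant allele) ~
  N(6, 2.5²), dichotomized at 6;
- baseline burden `bsum_mtv` log-normal with median 40 cm³, coupled to dCt
  through `log(bsum_mtv) = log 40 + 0.25·(dct − 6) + ε` (positive rank
  correlation, as observed clinically); dichotomized at 40 cm³;
- a PERCIST responder flag (rate 0.7) feeding a logistic model for the
  3-month non-progression label with intercept −0.22 and responder
  coefficient 3.22 (responder/non-responder non-progression probabilities
  ≈ 0.95 / 0.44);
- PFS and OS from a proportional-hazards model on the dichotomized flags —
  default hazard ratios 4.85 (high dCt) and 5.60 (high burden) for PFS and
  9.84 (high dCt) for OS — with an exponential baseline (Weibull shape
  configurable) whose reference stratum (all flags low) has median PFS 19.5
  and OS 30.9 months, and independent uniform censoring on [0, 33] months.

With ~50%-prevalence risk flags and hazard ratios of this size, the
cohort-wide marginal medians are necessarily shorter than the reference
stratum's; the generator's purpose is known structure for
parameter-recovery and calibration tests, not marginal curve matching.

## Problem sizes in the test and acceptance runs

Oracle-agreement checks use 200 random selection instances (≤ 10 lesions)
and 100 simulated cohorts of n = 60 for the cutoff search (plus one n = 200
cohort for change-point recovery); Cox recovery uses 200 replicates at
n = 500 with null coverage at n = 150; type-I calibration uses 500
replicates at n = 30–40 per group. These sizes give binomial/CLT error
bands comfortably tighter than the effects being checked.

## Known limitations

- SUL_max, not SUL_peak, drives classification (matching the analysis this
  package reproduces); SUL_peak is more reproducible on real images.
- Organ granularity is whatever the supplied label map encodes; paired
  organs should be distinct labels if the 2-per-organ cap is to treat them
  separately.
- No competing risks, time-varying covariates, or penalized regression in
  the survival stage; no adaptive or gradient-based segmentation.
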