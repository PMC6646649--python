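# Methods

This note documents the statistical procedures cadreader implements, the
modelling assumptions behind its synthetic-study generator, and the
numerical and design choices that were genuinely open.

## Study design being modelled

A sequential-design MRMC reader study: R radiologists each read the same C
exams twice — phase `pre` without CAD marks, phase `post` after the marks
(each a view, bounding box and 0–100 suspicion score) are revealed, with
the option to add or remove recalls. The case set is enriched: cancers are
biopsy-proven "prior" exams on which the lesion is retrospectively visible
and judged recallable (actionable), normals are confirmed by ≥2 years of
negative follow-up. Ground truth per cancer is a laterality, a quadrant and
per-view truth boxes adjudicated by validating radiologists; truth is an
input, never inferred.

## Detection metrics

* **True-positive rule.** A recall on a cancer is a true positive iff the
  claimed laterality and quadrant both equal the truth. The rule is a
  per-case localization criterion, deliberately coarser than a
  box-intersection criterion: readers report locations, not boxes. A
  location-agnostic switch exists because the per-class conversion tables
  count plain case-level recalls; it defaults off for CDRs and on
  (i.e. location-agnostic) for conversion accounting.
* **CDR** is TP/n_cancer on the enriched set — a per-case sensitivity. It
  is not comparable to clinical cancer-detection rates per thousand
  screens, and the package never reports it as such.
* **Conversion accounting** requires a *truth-hitting* mark (a mark whose
  box strictly overlaps a truth box on the same view) before a converted
  or ignored flag is counted: a reader who converts on a false mark that
  happens to sit on a cancer case is not credited as CAD-prompted
  detection.
* **Conservation identities** are asserted on every run:
  `fp_post = fp_pre + conversions − reversals` per reader, and per-class
  flagged misses split exactly into conversions plus ignored flags.

## Pooled ROC and AUC

The aggregate score of a case is the sum of the R binary recalls, an
ordinal rating in [0, R]. The empirical ROC sweeps thresholds over the
sorted unique scores in descending order, preceded by a sentinel above the
maximum, with recall iff score ≥ t; this anchors the curve at (0,0) and
(1,1) and handles ties without randomization (a tied block contributes one
vertex; the trapezoid through it equals the tie-corrected pair count).
AUC is the trapezoidal integral and provably equals the Mann–Whitney
statistic (#concordant + ½·#tied)/(n₁n₀); the equality is property-tested
against independent pair-enumeration and library oracles. The pooled score
sums raw recalls by default — the 0–R rating is defined as a sum of recall
decisions — with a localization-aware variant available for sensitivity
analyses.

The relative AUC change is 100·(post − pre)/pre, signed so that an
improvement is positive. The stand-alone CAD score of a case is the
maximum mark score (0 when unmarked). The theoretical-reader transform
sets post-recall := pre-recall OR case-has-any-mark, for cancers and
normals alike, never removing a recall; converted recalls claim the
truth-hitting mark's location when one exists, else the highest-scoring
mark's location (quadrant derived from the box centre by a fixed
partition of the 1000 px image: the middle 30 % band of both axes is
`central`, the rest splits by halves).

## Resampling inference

* **Case axis:** draw C cases with replacement; the aggregate scores per
  case are invariant, so replicates re-index the score vectors. Replicates
  containing a single truth class are *redrawn* (not skipped) and the
  redraw count is reported; with 90/32 cases the event has negligible
  probability, but the behaviour must be defined for small studies.
* **Reader axis:** draw R readers with replacement and re-sum the decision
  rows — a reader drawn twice contributes twice, keeping the score range
  [0, R]. Requires R ≥ 2.
* Replicate summary: mean μ, sd σ (ddof = 1), normal CI
  [μ − zσ, μ + zσ] with z fixed at exactly 2.58 for the 99 % level (the
  conventional printed multiplier, not 2.5758; other levels use the exact
  normal quantile), and the percentile CI alongside. "Significant" means
  the normal CI excludes 0. The RNG is numpy's seeded default generator;
  the seed is recorded in every result and identical seeds reproduce the
  replicate vector bit for bit.
* **One-sample t test** on per-reader deltas: t = mean/(sd/√n), df = n − 1,
  two-sided p from the t tail (scipy's regularized incomplete-beta
  evaluation). Zero-variance samples short-circuit with a warning: p = 1
  when the mean is also zero, else p = 0.

## Cohort ledger

"More than 270 days before biopsy" is a strict inequality (a 270-day gap
is not a prior). Stage percentages round to the nearest integer with ties
away from zero — the convention that reproduces 139/317 → 44 % and
90/139 → 65 %. Earliest-Actionable selection takes the minimum exam date
among an actionable patient's flagged priors, breaking date ties
lexicographically on exam id with a logged warning. Lead times are
reported from the selected exam to the *biopsy* date (the alternative —
to the current mammogram — is not computable from the schema) and
labelled as such. Partition identities
(actionable + non-actionable + excluded = retrospective;
retrospective + de-novo = with-priors; cancer + benign − both = total)
are asserted on every ledger build.

## Synthetic-study generator

The generator emulates the published study conditions; its defaults are
those conditions, not tuning knobs.

* **Case mix:** 90 cancers + 32 normals; density categories 1–4 with
  probabilities (4, 43, 37, 6)/90; lesion compositions drawn from the
  published frequency table, ordered leading-component-first so the
  calc/mass dichotomy splits 17/73 in expectation.
* **CAD model:** a truth-hitting mark with probability 0.98 (the reported
  stand-alone case-level sensitivity on this case set); Poisson false
  marks with mean 0.3 per cancer and 0.7 per normal; mark scores from
  normals clipped to [0, 100] — mean 80, sd 12 for truth-hitting marks and
  mean 55, sd 15 for false marks. Rates and score shapes beyond the 0.98
  are modelling choices (the published record gives only example scores);
  all are configuration, never hard-coded.
* **Reader model:** unaided recall ~ Bernoulli(sens_pre) on cancers and
  Bernoulli(fp_prob_pre) on normals, claimed location correct with
  probability localization_accuracy (default 1). In the CAD phase a
  recall survives unless the case is unmarked and the reader reverses
  (reversal_prob); a miss converts with probability compliance_correct
  given a truth-hitting mark, else compliance_false given any mark.
  Readers are conditionally independent given the case.
* **Calibration:** the default profile sets sens_pre and fp_prob_pre to
  the published per-reader marginals and solves compliance_correct,
  compliance_false and reversal_prob by bisection of the expected-count
  equations against the published conversion/reversal columns (bisection
  rather than the closed form so the same helper serves non-linear
  targets; unreachable targets clip to 1 with the boundary value).
* **Randomness discipline:** one RNG stream for cases, one for marks, one
  per reader, derived by stable sub-seeding — changing a reader's
  parameters perturbs nothing else. Each reader draws a fixed block of
  four uniforms per case whether or not each is consumed, so raising a
  compliance probability converts a superset of cases under the same
  seed; the monotonicity is deterministic, not merely statistical.

**What the generator does not emulate,** and hence what passing tests do
not establish about real data: inter-reader correlation beyond the shared
case (real readers err on the same hard cases, which widens reader-axis
variability and lowers the pooled AUC — the simulated pooled baseline AUC
runs high relative to an equally-sensitive correlated panel, and the
case-axis 99 % significance of the AUC gain therefore reproduces for most
but not all seeds); reading order, fatigue and the laboratory effect;
lesion-conspicuity correlation between readers and CAD; per-lesion (FROC)
structure within a case. The cohort generator produces exact configured
stage counts, so ledger tests exercise the accounting, not sampling
variability.

## Numerical conventions and degenerate inputs

* All internal arithmetic is unrounded; display rounding is centralized
  (decimal half-away-from-zero) and applied once at formatting time.
* Box overlap demands strictly positive intersection area; edge-touching
  boxes do not overlap. Coordinates are 0-based pixels, x rightward,
  y downward, boxes corner + extent.
* Metrics with an empty denominator class raise `UndefinedMetricError`;
  a zero-baseline relative change is reported absent with a warning
  rather than infinite.
* The ROC requires both truth classes; an all-tied score vector yields the
  diagonal chord and AUC ½ without special-casing.
* Synthetic scale in the test suite: the full study scale (122 cases,
  7 readers, two B = 10,000 bootstraps) is exercised directly; generator
  parameter recovery uses 5,000 cancers, at which the binomial SE of a
  sensitivity estimate is ≈ 0.007 against a ±0.02 tolerance.

## Known limitations

* No variance-component MRMC models (Obuchowski–Rockette,
  Dorfman–Berbaum–Metz) and no BCa bootstrap intervals; the implemented
  case/reader bootstraps answer the narrower question of CI coverage for
  the pooled-AUC change.
* No per-lesion FROC analysis, reading-time analysis, or image handling
  of any kind; truth and marks enter as tabular geometry only.
* The localization rule for the published conversion tables is not
  recoverable from the printed record; both modes are provided and the
  default is documented above.
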