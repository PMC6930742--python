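# Methods

## The classification problem

Idiopathic tinnitus has been associated with gray-matter (GM) volume
changes in a scattered, inconsistently replicated set of cortical and
subcortical regions. The approach implemented here treats biomarker
discovery as a supervised classification problem: each subject is
described by the GM volumes (mm³) of 61 candidate regions of interest
(ROIs) collated from earlier morphometry studies — 5-mm-radius spheres
centered on published MNI peak coordinates — and a feature-selection +
classification pipeline is asked to find the subset of regions that
separates patients from healthy controls.

The pipeline is a hybrid of a *filter* and a *wrapper*:

1. **Filter (F-score).** For feature *i* with group means x̄ᵢ⁺, x̄ᵢ⁻ and
   whole-sample mean x̄ᵢ,

       Fᵢ = [(x̄ᵢ⁺ − x̄ᵢ)² + (x̄ᵢ⁻ − x̄ᵢ)²] / [s²₊ + s²₋],

   where s²₊ and s²₋ are the unbiased within-group variances. Features
   are ranked by descending Fᵢ. The statistic is affine-invariant and
   symmetric under group exchange; both properties are pinned by tests.

2. **Wrapper (SFFS over an RBF-SVM).** Starting from the empty set at
   the inner-CV majority-class baseline, ranked features are tentatively
   added one at a time. After each addition all 121 (C, γ) pairs with
   log₂C, log₂γ ∈ {−5, …, 5} are evaluated by 5-fold cross-validation on
   the training set, for the soft-margin SVM with kernel
   K(x, y) = exp(−γ‖x − y‖²). The feature is kept only if the best
   inner-CV accuracy *strictly* increases; a tie rejects. Every feature
   is visited exactly once. The default is this forward-with-rejection
   procedure; a full floating variant (backward removal passes after
   each acceptance, kept only on strict improvement) is available via
   `floating=True`.

3. **Nested evaluation.** The cohort is split into 5 class-stratified
   outer folds (for 46 patients / 56 controls: 10+12, 9+11, 9+11, 9+11,
   9+11 subjects, i.e. 22/20/20/20/20). Per outer fold, the F-score
   ranking, all SFFS decisions, the hyperparameter search and the
   feature standardization statistics use the training subjects only;
   the refit classifier scores the held-out fold. Held-out decision
   values are pooled across folds into one out-of-fold score per
   subject for the ROC/AUC. A leakage test perturbs the held-out rows
   of a fold and asserts the fold's ranking, trace and selected set are
   unchanged.

## Synthetic cohort generator

The clinical cohort is not deposited, so the generator reproduces the
statistical structure the analysis assumes, parameterized by the
published per-group statistics:

- **Signal regions** (13): per-group Gaussian volumes at the published
  means/SDs. One published region (left rostral middle frontal gyrus)
  prints identical statistics for both groups and therefore carries no
  signal; it is reproduced as printed. `effect_scale` multiplies each
  mean difference about the midpoint of the two group means (0 = null
  cohort, 1 = as published, 2 = doubled effects).
- **Null regions** (48, named after the remaining catalogue ROIs):
  one Gaussian shared by both groups, mean drawn uniformly from
  80–550 mm³ (the span of the published signal means), SD = 0.13 × mean
  (the published median coefficient of variation).
- **Correlation.** Regions are independent by default — the simplest
  model consistent with published means ± SDs. An exchangeable
  correlation ρ ∈ [0, 1) can be switched on for robustness experiments
  (implemented as a shared per-subject factor, so the covariance is
  positive-definite by construction).
- **Covariates.** Age uniform on 22–64 years; sex Bernoulli with 40 %
  male (the published cohort proportions); neither influences volumes,
  matching the generator's scope.
- **THI scores.** Each patient is assigned a severity band (mild 1–16,
  light 18–36, moderate 38–56, severe 58–76, catastrophic 78–100;
  uniform by default) and an even score within it (THI items score
  0/2/4, and the published range 0–98 is even). Within one focus band
  the score can be tied to a named region's standardized volume at a
  target Pearson r through a bivariate-Gaussian construction; clipping
  to the band and rounding to the even grid attenuate the realized
  correlation by ≈ 1–2 %, which is inside the Fisher-z noise at any
  realistic band size. Controls carry no score.
- Volumes are floored at 1 mm³ (physical positivity; flooring is logged
  and essentially never triggers at the published parameters).
  Generation is a pure function of the config including its seed;
  byte-identical tables are asserted in tests.

What the generator deliberately does **not** emulate: inter-region
correlation of real morphometry (default), age/sex effects on volume,
segmentation/normalization artifacts, and site or scanner effects.
Passing tests therefore certify the *procedure* — its determinism,
leakage-freedom, calibration under the null, and recovery of planted
effects — not the clinical numbers of any real cohort.

## ROI volumetry

ROI masks are built in each GM map's native grid from the NIfTI header
affine; no resampling, smoothing or thresholding. A voxel belongs to a
mask when its center lies within Euclidean distance ≤ r of the peak (a
closed ball — chosen so the radius-equals-zero-distance case is
unambiguous). The ROI volume is Σ(GM value) × voxel volume. Tests pin
the masks to an every-voxel brute-force oracle and, for 1-mm unit maps,
to the lattice-point count ‖(i,j,k)‖² ≤ r². The shipped catalogue holds
the 61 unique peak coordinates; three peaks that the published peak table lists
under two labels (superior vs middle temporal gyrus) appear once, with
the alternate label recorded.

## Numerical and design choices

- **Kernel sign.** The original report prints the RBF kernel without a negative
  exponent; the standard exp(−γ‖·‖²) is implemented (the printed form
  diverges with distance and cannot be a similarity).
- **Standardization.** Features are z-scored before SVM fitting —
  necessary because volumes span ~89–504 mm³ and the RBF kernel is
  scale-sensitive. Statistics come from the outer-fold training set and
  are computed once per fold, shared by the inner folds. This keeps the
  squared distance of a feature subset equal to the sum of per-feature
  distance matrices, so SFFS candidates reuse precomputed matrices; the
  alternative (re-estimating scales inside every inner fold) changes
  accuracy estimates by far less than their fold-to-fold noise and
  touches no held-out data either way.
- **Degenerate F-scores.** Zero within-group variance in both groups
  gives F = 0 when the group means agree and +∞ (ranked first) when
  they differ, preserving "larger = more discriminative".
- **Ties.** Ranking ties break by ascending feature index; grid-search
  ties prefer the smallest C, then the smallest γ (the smoother model).
- **Empty-set baseline.** The SFFS starting accuracy is the inner-CV
  majority-class rate; if nothing beats it (null-like data) the fold
  predicts the training majority with decision score 0.
- **Aggregation.** Published headline accuracies are read as means over
  the 5 outer folds. Because each fold may select a different subset,
  the "final" feature set is reported as the consensus of regions
  selected in ≥ 3/5 folds, alongside all per-fold sets — the original report
  reports a single 13-region set without stating its aggregation rule,
  so this is a documented choice, not an inference of intent.
- **Age control.** An optional pre-step residualizes each feature on a
  linear age fit estimated on the training fold only; off by default
  (the original report mentions controlling for aging without describing a
  method).
- **ROC scores.** Continuous decision values pooled out-of-fold; Platt
  calibration is not applied (per-fold ROC is rank-invariant to it, and
  the pooled curve is reported as the raw procedure produces it).
- **SVM backend.** The inner loop (≈ 184,000 SVM fits per cohort:
  5 outer folds × 61 candidates × 121 grid pairs × 5 inner folds) calls
  scikit-learn's bundled libsvm binding directly on precomputed
  kernels, reconstructing decision values in the public-API convention;
  a regression test pins exact agreement with `SVC` on random problems,
  and the code falls back to `SVC` when the binding is unavailable.
  This turns one full nested cohort run into ≈ 20–30 s on one CPU.
- **Seeds.** One master seed derives every stage seed (cohort, THI,
  outer folds, per-fold inner folds, replicates) via CRC-32-tagged
  `SeedSequence`s; the scheme is stable and all derived seeds are
  below 2³¹.

## Problem sizes used by the test and acceptance runs

The stochastic suites use 10 replicate cohorts for the headline
reproduction, 10 for the null calibration (effect_scale = 0) and 12 for
the planted-recovery analysis (effect_scale = 2), all at the full
46/56 × 61 geometry; unit and property tests run on miniature cohorts
(10–30 subjects, 4–8 regions). These sizes keep the complete suite
around 20 minutes on a single CPU while leaving the Monte-Carlo error
of each reported mean well inside the tolerances being checked.

## What the reproduction shows — a known limitation

Under the generator's independence assumptions the published headline
numbers are not reachable, and the package reports this rather than
hiding it. The generating distribution itself fixes a ceiling: with the
published per-region means/SDs, the squared standardized group
separation sums to d² ≈ 2.41 (d ≈ 1.55), so the *Bayes-optimal*
classifier of the synthetic model attains ≈ 78 % accuracy and AUC
≈ 0.86 — and any classifier trained on 102 subjects, with feature
selection over 48 nulls and noisy 5-fold estimates, must land below
that. The replicate driver (`analysis/04_replicate_study.py`) and the
acceptance script measure where the honest nested procedure actually
lands: mean held-out accuracy ≈ 0.66, mean inner-CV (training)
accuracy ≈ 0.87 (upward-biased, being a maximum over 121 grid pairs),
pooled AUC ≈ 0.70. The published pattern (training 80.49 %, test
80.00 %, AUC 0.8586) — test essentially equal to training, one global
feature set and one (C, γ) — is characteristic of selection performed
without outer-fold isolation, and/or of real-data inter-region
correlations that the independence model lacks. The generator's
parameters are the published statistics and were not adjusted to close
this gap.

Other known limitations: severity-band correlations are validated on
planted synthetic associations, not clinical ones; the ROI stage
consumes already-segmented, MNI-space GM maps (no VBM preprocessing);
no alternative classifiers or search strategies are provided.
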