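# tinnisel

Selection of morphological brain-region biomarkers that separate
idiopathic tinnitus patients from healthy controls, via a hybrid
**F-score filter + sequential forward floating selection (SFFS) +
RBF-SVM wrapper** with nested 5-fold cross-validation — plus a
synthetic cohort generator so the whole pipeline is testable without
access to the original (undeposited) MRI cohort.

Intended users: neuroimaging researchers who want a tested, leakage-free
reference implementation of this family of filter+wrapper SVM pipelines,
and methodologists who want to study its statistical behavior (null
calibration, planted-effect recovery, selection-bias of inner-CV
estimates) under controlled synthetic conditions.

## The method

Each subject is described by gray-matter volumes (mm³) of 61 regions of
interest — 5-mm spheres at published MNI peaks (shipped catalogue).
Per outer fold of a class-stratified 5-fold split (22/20/20/20/20
subjects for the 46-patient / 56-control reference cohort):

1. every feature *i* is scored on the training subjects by the
   two-group F-score

   F_i = [(x̄_i⁺ − x̄_i)² + (x̄_i⁻ − x̄_i)²] / [s²₊ + s²₋]

   and features are ranked by descending F_i;
2. SFFS visits features in rank order: each candidate is tentatively
   added, the soft-margin SVM with kernel K(x,y) = exp(−γ‖x−y‖²) is
   re-tuned over the 11 × 11 grid log₂C, log₂γ ∈ {−5..5} by inner
   5-fold CV, and the candidate is kept only if the best inner-CV
   accuracy strictly increases;
3. the final classifier is refit on the whole training fold and scored
   on the held-out fold; held-out decision values are pooled across
   folds into one ROC/AUC over all subjects.

Because the clinical cohort is unavailable, `tinnisel.cohort` simulates
cohorts with the statistical structure the analysis assumes: 13 signal
regions drawn as per-group Gaussians at the published means ± SDs and
48 group-identical nuisance regions, with optional THI severity scores
correlated to a named region's volume inside one severity band.

## Worked example

```
$ python analysis/01_simulate_cohort.py
wrote 46 patients + 56 controls x 61 regions to results/cohort_seed1.csv
region                                       sim TP   pub TP   sim HC   pub HC
R_hypothalamus_5_-5_-11                       351.0    349.0    377.8    383.5
L_hypothalamus_-4_-10_-6                       89.4     89.4     95.1     95.9
...
patient THI: range 4-96, mean 51.4 +/- 29.2

$ python analysis/02_rank_features.py
top 10 regions by F-score:
   1. R_middle_temporal_gyrus_49_-70_13             F=0.1671 [signal]
   2. L_hypothalamus_-4_-10_-6                      F=0.0972 [signal]
   3. R_cingulate_gyrus_4_49_-5                     F=0.0858 [null]
   ...
7 of the top 13 ranked regions are published signal regions
```

The simulated group means land on the published parameters to within
sampling error, and regions with real group differences rise to the top
of the F-score ranking while 48 null regions fill the tail — at this
cohort size (n = 102) a handful of nulls inevitably outrank weak signal
regions, which is exactly the selection noise the nested evaluation has
to contend with.

`python analysis/03_nested_selection.py` then runs the full nested
procedure on that cohort (≈ 30 s):

```
per outer fold:
  fold 0:  5 features, (C, gamma) = (16, 0.125), train 0.8888, test 0.5909
  fold 1: 10 features, (C, gamma) = (1, 0.0625), train 0.8662, test 0.7000
  ...
means: train 0.8757  test 0.6382  AUC 0.7189
consensus features (>= 3/5 folds): ['L_hypothalamus_-4_-10_-6',
 'R_middle_temporal_gyrus_49_-70_13', 'L_inferior_temporal_gyrus_-62_-12_-26',
 'L_parahippocampal_gyrus_-20_2_-23']
```

and `python analysis/04_replicate_study.py` repeats the whole study
over 10 derived seeds (≈ 5 min) to produce the headline aggregate:

```
train accuracy 0.8734 +/- 0.0275
test accuracy  0.6698 +/- 0.0820
AUC            0.7013 +/- 0.0903
mean selected set size per fold: 8.8
```

with the left hypothalamus — the region with the largest standardized
group difference — selected in 44 of the 50 fold-level runs. Note the
large train–test gap: the training figure is a maximum over 121 grid
pairs of noisy 5-fold estimates and is therefore upward-biased, while
the held-out figure is honest. Under the generator's independence
assumptions even the Bayes-optimal classifier caps at ≈ 78 % accuracy
/ 0.86 AUC, so these replicate means — not the original report's 80 %
/ 0.8586 — are what an isolated, leakage-free run of this procedure
can deliver at the published effect sizes; see `docs/methods.md` for
the full analysis.

`python analysis/05_thi_correlations.py` exercises the severity-band
correlation machinery on a cohort with a planted light-band
association (target r = 0.83 recovered as r = 0.92 at n = 15, inside
Fisher-z noise).

A `tinnisel` CLI exposes the same stages (`simulate`, `extract-roi`,
`rank`, `select`, `evaluate`, `correlate`, `replicate`, `run`) on
persisted intermediates; `tinnisel run --config config.yaml` executes
everything and writes a reproducibility manifest.

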