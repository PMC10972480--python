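# Methods

## Problem and model

`dyadmet` frames the detection of vertical metabolome transfer as binary
classification: true mother–child dyads (label 1) versus random
mother–child pairings (label 0). Each pair is summarised per metabolite by
the sample standard deviation of the two within-cohort min–max-scaled
concentrations, s = |x_mother − x_child| / √2. If a metabolite's
concentration is transmitted — through pregnancy, breastfeeding, shared
environment, genetics, or the microbiome — true pairs sit systematically
closer on that coordinate than shuffled pairs, and a classifier picks the
signal up without any distributional assumptions per metabolite.

Population std (|a − b| / 2) would be an equally valid aggregation; both
are monotone in |a − b|, so the choice only rescales features. The sample
convention (ddof = 1) is used and logged.

## Preprocessing

Fixed order: missingness filter → detection-limit imputation → scaling →
variance filter → correlation filter. Choices that matter:

- **Missingness** (default threshold 0.33, strict "over"): a metabolite is
  dropped from *both* cohorts if it breaks the threshold in *either*,
  because dyad features need both values. Filters generally use both
  cohorts jointly (pooled values for variance and correlation) so the two
  matrices keep identical metabolite sets; per-cohort variants would let
  the sets drift apart.
- **Imputation** (default fraction 0.1): missing cells become 0.1 × the
  metabolite's smallest observed concentration in the same matrix, treating
  missingness as left-censoring at the detection limit. A minimum of 0
  imputes 0 with a logged warning.
- **Scaling** is fit per cohort (mothers among mothers, children among
  children): a scaled value is a position within its own cohort's range,
  which makes the dispersion feature a *relative-position* discrepancy and
  removes age-specific abundance shifts. Constant columns map to 0. Pooled
  scaling is available (`pooled_scaling`) for sensitivity analysis.
- **Variance filter** drops the floor(0.10 · m) lowest-variance metabolites
  (pooled, scaled); ties keep the earlier column.
- **Correlation filter** removes greedily in column order at |r| > 0.9;
  absolute correlation is used because anticorrelated duplicates are
  equally redundant.
- Preprocessing is fit on the full dataset before the train/test partition
  (the partition happens at the dyad level). A train-only-fit mode exists
  (`train_only_fit`) but is off by default; since scaling is rank-preserving
  per metabolite the practical leakage is minor, and the acceptance null
  benchmark confirms calibration.

## Dyad construction and the train/test design

Random dyads: each of `n_shuffles` (default 2) rounds draws a uniform
permutation pairing every mother with a child; a round that recreates a
true family pair or duplicates an earlier pair is re-drawn, so label 0 is
never contaminated (`allow_true_pair_collisions` disables the re-draw).
The pooled rounds are thinned by dropping round(0.30 · count) rows
uniformly at random, giving the ≈ 1 : 1.4 class ratio.

**Partitioning.** By default the *families* are split 80/20 first and true
and random dyads are then built independently within each side
(`group_split = True`). The alternative — building all dyads first and
splitting rows stratified by label — is implemented
(`group_split = False`) but was found to be miscalibrated: with no planted
signal, all three model families score systematically *negative* test MCC
(≈ −0.15 to −0.3). The mechanism is subject memorization: a random test
row whose child (or mother) had its true dyad in the training rows attracts
a false positive, while a true test row whose subjects appeared in training
only inside random dyads is pushed toward label 0. Partitioning by family
removes every shared-subject channel; under the null the test MCC is then
centred on 0 (verified in the acceptance suite). The row-level mode is kept
for leakage-sensitivity analysis.

## Models and evaluation

Three families behind one interface: `RandomForestClassifier`,
`LGBMClassifier`, and elastic-net logistic regression (saga solver, both L1
and L2 penalties via `l1_ratio`). Scoring is the Matthews correlation
coefficient; a zero denominator yields 0 by convention, and reports annotate
MCC > 0.2 as "above random (fair agreement)". Cross-validation is
stratified 10-fold ("10 ×" is read as 10-fold, not 10 repeats;
configurable). Confusion counts use the 0.5 probability threshold; AUC is
rank-based with ties averaged.

Hyperparameters are tuned by maximizing mean CV MCC with a small in-package
sequential optimizer: a Gaussian-process surrogate (Matern-5/2 + white
noise) over the unit hypercube, expected-improvement acquisition over a
random candidate pool, the family's default configuration evaluated as the
first trial (so tuning can never end below the defaults on the same folds).
Default search spaces are compact, desk-scale expert ranges — RF: 100–250
trees, depth 3–14, min leaf 1–10, feature fraction 0.02–0.3; LGBM: 7–31
leaves, learning rate 0.01–0.3 (log), 50–200 trees; elastic net: C
10⁻³–10³ (log), l1_ratio 0–1 — chosen so the full tuning × CV × selection
design runs comfortably at the benchmark problem sizes (hundreds of dyads,
~200 metabolites); all spaces are overridable per call.

## Feature selection

Multistage post-hoc permutation importance on the training table only.
Per stage: refit under stratified CV; on each fold's *validation* part,
permute one feature at a time (5 repeats) and record the drop in MCC;
average over folds and repeats; keep the top ceil(0.33 · n) features (ties
broken by name for determinism). Stopping: (a) the new stage's CV MCC does
not exceed the previous stage's by more than 10⁻³ (float-jitter guard,
configurable), (b) the cut would undershoot the floor of 7 features — then
exactly the top 7 are kept and scored as a final stage, or (c) 7 stages.
The returned set is the feature set of the best-CV stage. Permutation
streams are keyed by feature *name*, making importances invariant to column
order. Out-of-fold permutation avoids the optimism of permuting on the fit
data. Hyperparameters are frozen from the initial tuning across stages
(`retune_per_stage` exists for the alternative).

## Attributions

Exact Shapley values per prediction, no sampling:

- **Random forest**: per-tree decomposition over leaves. Conditioning on a
  feature subset S fixes the path splits on S (indicators) and marginalises
  the others by training cover fractions, so each leaf contributes a product
  game; its Shapley values follow from a symmetric-polynomial recursion
  (build the elementary-symmetric coefficients over path features, unwind
  one feature by polynomial division, apply the k!(p−1−k)!/p! weights).
  Attributions live on the probability scale and satisfy local accuracy
  (base + row sum = predict_proba) to ~10⁻⁹; the implementation is verified
  against a brute-force subset-enumeration oracle in the test suite.
- **LightGBM**: the booster's native per-prediction contributions, on the
  raw log-odds scale.
- **Elastic net**: φ_i = w_i (x_i − E[x_i]) on the decision-function scale,
  with the background mean taken from the supplied reference data
  (defaults to the explained matrix).

On dispersion features, a *low* value means mother and child agree; for a
transferred metabolite the attributions therefore correlate negatively with
the feature value — blue (low) points on the positive side of the beeswarm.

## Statistics

Welch (unequal-variance) t-tests per metabolite between true and random
dyads — group variances differ by construction, so the pooled-variance
Student test is not assumed — with Benjamini–Hochberg step-up adjustment
across metabolites (statsmodels) and significance at adjusted p < 0.05.
Zero-variance features get t = 0, p = 1, flagged. Tests run on all surviving
metabolites, not just the selected set, as an independent cross-check of the
ML selection. Outcome association uses two-sided Mann–Whitney U between
predicted-membership groups on test children only (per child, mean predicted
probability across its test rows, thresholded at 0.5); exact null
distribution for small tie-free samples, tie-corrected normal approximation
otherwise; raw p-values, no multiplicity adjustment across the handful of
outcomes.

## Synthetic generator

Mother log-concentrations are Normal(μ, σ) per metabolite (log-normal
concentrations capture metabolomics positivity and right skew). A heritable
metabolite with coupling β gives the child
c = μ + β(m − μ) + √(1 − β²)·σ·z, so corr(m, c) = β and the child marginal
is *identical* to the mother marginal whatever β — any dyad signal lives
purely in the coupling, which is exactly what the classifier is supposed to
detect, and marginal-based shortcuts are impossible by construction.
Missingness is MCAR at a configurable rate (default 5 %); an optional
left-censoring mode (`censor_quantile`) emulates detection-limit
missingness but is off by default for analytic tractability. A configurable
fraction of metabolites are unannotated ("X-####", class Unknown) and a
fraction are classed Xenobiotics. Outcomes (infection-like counts plus a
CRP-like marker) are null by default; a nonzero `outcome_effect` shifts
them with the child's heritable-metabolite concordance.

What the generator does *not* emulate: correlated metabolite blocks
(pathways), batch effects and drift, cohort-specific abundance structure,
non-Gaussian coupling, informative missingness. Passing benchmarks
therefore show the machinery recovers planted coupling under clean
conditions; they do not certify effect sizes on real cohorts.

Benchmark sizes (300 families × 200 metabolites, 10 planted at β = 0.9,
tuning budget 10 trials; nulls at β = 0) were chosen as the package's
standard benchmark conditions; the test suite and `scripts/acceptance.py`
state the sizes they use in their reports.

## Numerical and degenerate-case choices

- MCC zero-denominator → 0; leave-one-out CV is rejected (per-fold MCC
  undefined on singletons).
- Min–max scaling of a constant column → 0; imputation with observed
  minimum 0 → 0 with warning.
- Variance-filter ties keep the earlier column; correlation filter is
  greedy in column order; importance ties rank by feature name.
- Selection floor: when the 33 % cut would undershoot 7 features, exactly
  the top 7 are kept; when the current set is already at the floor the loop
  stops without a duplicate stage.
- Stage sub-seeds derive from the master seed via `SeedSequence`, so each
  stage is independently reproducible and all derived seeds stay < 2³¹.

## Known limitations

- Singleton dyads only: one mother and one child per family; no fathers,
  twins, or longitudinal multi-timepoint dyads.
- Exact forest attributions cost O(trees × leaves × p²) per batch and are
  intended for the compact post-selection models, not for hundreds of
  features.
- The elastic-net path reports attributions on the margin scale, not the
  probability scale.
- Starts from quantified metabolite tables; no raw spectra handling, batch
  correction, or drift correction.
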