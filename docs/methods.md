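# Methods

`radsel` implements a complete two-group radiomic classification workflow:
a named feature universe, a synthetic cohort generator, a univariate
screen, all-relevant feature selection embedded in repeated cross-
validation, random-forest classification, and a permutation-calibrated
binomial test on selection frequency. This note records the statistical
model behind each stage, the defaults and why they were chosen, and what
the synthetic data does and does not establish.

## Feature universe

Features are identified as `tissue.hemisphere.label.measure.statistic`
(lowercase, dot-joined — greppable, sortable and CSV-header-safe). The
default universe has 2,084 features:

- **Gray matter (1,316).** 62 DKT cortical regions (31 per hemisphere)
  × 5 vertex-wise shape measures (local thickness, geodesic depth, travel
  depth, mean curvature, convexity) × 4 distribution statistics (mean, SD,
  kurtosis, skewness) = 1,240, plus 62 cortical and 14 subcortical volume
  scalars. The 1,240 + 76 decomposition is this package's construction —
  only the total of 1,316 is fixed by the workflow it models — and the
  counts are entirely config-driven, so other decompositions are
  expressible.
- **White matter (768).** 48 JHU-ICBM-81 tract labels × 4 diffusion
  measures (FA, MD, RD, AD) × the same 4 statistics. Unpaired tract
  labels (corpus callosum parts, fornix, the cerebellar/pontine midline
  structures) carry `hemisphere=midline`.

Two labeling quirks worth knowing: the atlas splits the internal capsule
into three limbs, so the default planted "internal capsule" effect uses
the anterior limb as representative; and the default effect list follows
the published feature table in using pars orbitalis (the accompanying text
says pars opercularis — the schema contains both regions and takes no
side).

## Synthetic cohort and feature tables

The generator emulates the study conditions the pipeline is meant for:
59 cases vs 69 controls, sex counts 47/12 and 58/11, and per-group normal
distributions for age and the four clinical scales (severity-of-use CIAS,
impulsivity BIS-11, anxiety SAS, depression SDS) at the published means
and SDs. Scale scores are continuous by default (`round_scales` switches
on integer rounding); they are summaries, not item-level questionnaires.

Feature tables plant the eight published discriminative effects at their
per-group means/SDs (standardized effects |d| ≈ 0.5–0.7); every other
feature is N(0, 1) identically in both groups. Null features carry
block-wise correlation (default: blocks of 16 consecutive features,
pairwise r = 0.3 via a one-factor construction, independent across
blocks) because radiomic features within a region/metric family are
correlated in real data; the value is a tunable default, not an empirical
claim. All marginals are Gaussian — the modeled study reports only
means ± SDs, and the pipeline consumes feature *values*, so
skewness/kurtosis-named features need no non-Gaussian pedigree.

What passing tests on this generator shows: the pipeline's type-I
behavior, its power against localized mean shifts of realistic size, and
the correctness of its accounting. What it cannot show: behavior under
real radiomic covariance (long-range correlation, site effects,
non-Gaussian tails), registration/segmentation artifacts, or
demographic confounding. Classification metrics obtained on synthetic
tables are properties of the generator, not estimates of any real
cohort's separability.

## Cohort statistics

Group comparisons reproduce the conventions that recompute the published
demographic tables exactly from their printed summaries:

- **Pooled (Student) t**, not Welch: sp² = ((n₁−1)s₁² + (n₂−1)s₂²)/(n₁+n₂−2),
  df = n₁+n₂−2 (= 126 at 59/69). The printed scale statistics (17.57,
  6.87, 6.09, 4.32) are reproduced only under pooled variance.
- **Pearson chi-square without continuity correction** for sex
  (47/12 vs 58/11 → χ² = 0.417, p = 0.518 only uncorrected).
- **Normality gate** for raw comparisons: one-sample KS against a normal
  with the sample's own mean/SD (the common applied usage, not
  Lilliefors), α = 0.05; failures fall back to two-sided Mann–Whitney U
  with tie-corrected normal approximation.
- Diagnostic rules: the 8-item questionnaire rule (items 1–5 all yes plus
  ≥1 of items 6–8) and the severity-scale cutoff between 63 and 64.

## Screening

Features are z-scored (sample SD) over the full table and filtered by
per-feature one-way ANOVA, keeping uncorrected p < α (default α = 0.05,
the mildest conventional screen; the workflow this models reports only
that 179 of 2,084 features survived on its data, which cannot anchor a
threshold). For two groups F = t² exactly, which the implementation uses
and the tests verify against an independent t-test. Z-scoring the full
table before CV leaks the held-out fold's scale into training; this is
kept deliberately for fidelity to the modeled workflow, and constant
columns are flagged rather than fatal.

## All-relevant selection (shadow features)

The selector is a from-scratch Boruta-style algorithm. Each iteration:
(1) append an independently shuffled shadow copy of every still-undecided
feature; (2) fit a random forest on the extended matrix (n_trees trees,
mtry = ⌊√p⌋); (3) a real feature scores a *hit* when its importance
strictly exceeds the best shadow importance of that iteration; (4) each
undecided feature's cumulative hit count is tested two-sided against
Binomial(iterations, ½) at α = 0.01 with a Bonferroni factor over the
currently undecided features (upper tail → confirmed, lower tail →
rejected); (5) stop when everything is decided or the iteration budget
(default 100) runs out. Remaining features are *tentative* and are not
selected — the workflow's relevant/irrelevant dichotomy maps tentative to
irrelevant, and no post-hoc rescue is attempted. Decided features
(confirmed and rejected) are dropped from subsequent forests, which
shrinks compute and lets weaker signals compete once dominant ones are
settled. Importance is the forest's impurity measure by default
(the common default of the R random-forest stack of this vintage);
permutation importance is available via `RFConfig(importance="permutation")`
at considerable extra cost. With fewer than five features the max-shadow
statistic is unstable, so the selector warns but still runs.

## Nested cross-validation

Repeated k-fold (k = 5, default 100 repeats → 500 iterations). For each
iteration the selector runs on the four training folds only; a random
forest with n_trees = 1000 and mtry = ⌊√p_selected⌋ is trained on the
confirmed features and evaluated on the held-out fold. Accuracy,
sensitivity (case = positive, the clinical convention), specificity and
Cohen's kappa are aggregated as mean ± SD over all iterations; undefined
ratios become NaN and drop out of that metric's aggregate only.

Folds are stratified by default although plain random partitioning is a
config switch: with a 59/69 imbalance, unstratified folds occasionally
produce degenerate test folds. Iterations whose selector confirms
nothing predict the training-fold majority class (flagged), keeping the
iteration accounting intact on null data.

## Selection-frequency inference

A feature selected in k of M iterations on the original labels is tested
against X ~ Binomial(M, p₀). p₀ is estimated by rerunning the identical
selection-inside-CV pipeline on label-permuted copies of the screened
table and pooling selection frequencies over *all* features and
permutations into one global mean (a single-parameter null; a per-feature
null is a config option). Upper-tail p-values are computed via the
binomial survival function (verified to ≥12 digits against exact
rational-arithmetic summation), Bonferroni-adjusted over the
screen-surviving family, and a feature must additionally be selected in
at least half the original iterations (the minimum-frequency floor).
Hit counts are recovered as round(freq × M) so serialized frequencies
round-trip.

Two design choices here were genuinely open. First, each permuted
dataset is processed by the *full* pipeline — the univariate screen is
redone under the permuted labels and selection runs on that
permutation's own survivors. This matters: the original run's screen
sees the full table (leakage, below), so a null calibration whose
permuted runs skip the screen would be structurally less leaky than the
run it calibrates and would underestimate p₀. Pooling frequencies over
each permutation's own screened family makes p₀ the chance selection
rate of *a feature that entered selection*, which is the family the
observed frequencies are tested in. Second, the permuted runs may use
fewer CV repeats than the original run (`perm_cv_repeats`): p₀ is a
per-iteration rate, so a shorter permuted run estimates the same
parameter with less compute; the binomial M is always the original
run's iteration count.

## Desk-scale defaults and problem sizes

The full-scale protocol (2,084 features, 500 CV iterations, 1,000
permutations each wrapping a full CV) is far beyond interactive use, so
the package ships reduced run scales used by the test suite and the
acceptance script:

- planted-effect runs use `compact_schema()` — a 288-feature universe
  containing all eight planted effects — with 5×5 CV, 50-tree forests,
  selector budget 50 iterations, and 8 permutations with 5×1 CV inside;
- all-null runs keep the **full** 2,084-feature universe (see below) with
  5×5 CV, selector budget 30, 4 permutations.

The selector's iteration budget matters for power (confirmation at level
α/(2m) needs a hit fraction that falls as the budget grows), which is why
the planted scale uses 50 rather than the ~15 that suffices for
rejection. The null scale keeps the full universe because the
procedure's type-I behavior depends on the *size of the screened
family*: with only a handful of screen survivors the max-shadow bar is
trivially low and the selector's sequential binomial inflates badly,
a regime the full-scale funnel (about a hundred survivors of 2,084)
never enters. Shrinking the feature universe for null experiments
silently changes the question being asked.

## Numerical notes and limitations

- All randomness flows from a master seed through named substreams
  (cohort, features, cv, permutations), so any stage can be rerun in
  isolation and end-to-end runs are bit-reproducible.
- Ties in forest importances break in favor of the shadow (a hit requires
  strictly greater importance); constant features z-score to zero and are
  screened out; a degenerate p₀ = 0 null makes p-values 0/1 indicators
  and is flagged.
- The binomial null treats CV iterations as independent trials; they are
  not (folds share subjects), so the null is approximate by construction —
  the permutation calibration absorbs most, not all, of that dependence.
- **Family-wise error under a global null is not fully controlled.**
  Because the screen runs on the full table, roughly one in five all-null
  realizations contains a chance feature (|t| approaching 4.4 among 2,084
  tests at n = 128) that stays discriminative inside every training fold,
  is selected in at least half the CV iterations, and cannot be explained
  by the pooled-*mean* binomial null (label permutation destroys the
  leak, so p₀ ≈ 0.005 while the feature's observed frequency exceeds
  0.5). A null based on the permutation distribution of the *maximum*
  selection frequency would flag such features as chance; the
  mean-binomial construction implemented here follows the modeled
  workflow and inherits this blind spot. Findings with selection
  frequencies near the 0.5 floor deserve corresponding skepticism.
- Only binary group labels are supported; no multi-class selection, no
  covariate adjustment in the screen, no FDR alternatives as defaults,
  and no image processing of any kind.
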