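# radsel

All-relevant radiomic feature selection with permutation-calibrated
selection-frequency inference, for discriminating two subject groups from
brain-derived feature tables.

## The problem

Radiomic studies of psychiatric and neurological conditions reduce
structural and diffusion MRI to thousands of named regional features
(cortical shape statistics over an atlas parcellation, per-tract summaries
of diffusion scalars) and ask two questions: *can the groups be told
apart*, and *which features carry the signal*. With ~2,000 features and
~130 subjects, answering the second question honestly requires selection
to happen inside cross-validation and significance to be calibrated
against chance selection. `radsel` packages that workflow for
methodologists and imaging groups who have a subjects × features table
(CSV/TSV with a `group` column) — or who want to study the workflow itself
on synthetic cohorts with known planted effects.

## The method

1. **Screen.** Features are z-scored and filtered by per-feature one-way
   ANOVA (for two groups, F = t²), keeping uncorrected p < α.
2. **Select inside CV.** Repeated stratified k-fold (k = 5). On each
   iteration's training folds, a Boruta-style all-relevant selector
   appends a shuffled *shadow* copy of every undecided feature, fits a
   random forest (mtry = ⌊√p⌋), scores a feature a hit when its importance
   beats the best shadow, and decides confirmed/rejected by a two-sided
   Binomial(iterations, ½) test on cumulative hits. A forest trained on
   the confirmed features is evaluated on the held-out fold; accuracy,
   sensitivity, specificity and Cohen's κ aggregate as mean ± SD over all
   k × repeats iterations.
3. **Calibrate and test.** A feature selected in k of M iterations is
   tested against X ~ Binomial(M, p₀), with p₀ the mean selection
   frequency over label-permuted reruns of the identical pipeline.
   Upper-tail p-values are Bonferroni-adjusted over the screened family,
   and features selected in fewer than half the original iterations are
   excluded regardless of p.

The synthetic module generates the reference cohort this workflow is
studied on: 59 cases vs 69 controls with published demographic and
clinical-scale distributions, and feature tables with eight planted
group effects (|d| ≈ 0.5–0.7) in block-correlated Gaussian noise.
See `docs/methods.md` for assumptions and design choices.

## Worked example

```python
from radsel import RunConfig, run_pipeline, simulate_dataset
from radsel.simulate import compact_schema

cfg = RunConfig(seed=1, cv_repeats=5, n_trees=50, selector_max_iter=50,
                n_permutations=8, perm_cv_repeats=1)
demo, table = simulate_dataset(cfg, compact_schema())   # 128 x 288, 8 planted effects
result = run_pipeline(table, cfg)
m = result.cv_result.summary.mean
print(f"accuracy {m['accuracy']:.3f}  kappa {m['kappa']:.3f}")
print(f"null rate p0 = {result.null_model.p0:.4f}")
print(result.report.table.head(4)[["observed_freq", "adjusted_p", "significant"]])
```

prints

```
accuracy 0.781  kappa 0.555
null rate p0 = 0.1542
                                                        observed_freq    adjusted_p  significant
feature_id
gray.left.rostral_middle_frontal.local_thickness.std             1.00  9.120256e-20         True
gray.left.rostral_middle_frontal.travel_depth.skewness           1.00  9.120256e-20         True
gray.left.fusiform.local_thickness.skewness                      1.00  9.120256e-20         True
gray.left.cuneus.local_thickness.mean                            0.96  1.259397e-17         True
```

The pipeline screened 288 features down to 18, ran the selector inside
5×5 cross-validation, estimated a chance selection rate of ~15% from
eight label-permuted full-pipeline reruns, and declared four planted
features significant — each selected in (nearly) every iteration, which
chance cannot explain even after the 18-fold Bonferroni factor.

The same stages are exposed as a CLI:

```sh
radsel simulate --seed 1 --outdir data/
radsel run --features data/features.csv --seed 1 --outdir out/
radsel stats data/demographics.csv
```

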