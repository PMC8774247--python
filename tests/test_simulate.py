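"""Synthetic cohort/feature generator: moments, determinism, permutations."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from radsel.schema import SchemaConfig, build_default_schema
from radsel.simulate import (
    DEFAULT_EFFECTS,
    CohortConfig,
    EffectSpec,
    NoiseConfig,
    generate_cohort,
    generate_feature_table,
    permute_labels,
)
from radsel.tables import CASE, CONTROL


class TestCohort:
    def test_default_cohort_has_study_composition(self, cohort):
        assert len(cohort) == 128
        assert (cohort["group"] == CASE).sum() == 59
        assert (cohort["group"] == CONTROL).sum() == 69

    def test_sex_counts_match_config_exactly(self, cohort):
        case = cohort[cohort["group"] == CASE]
        ctrl = cohort[cohort["group"] == CONTROL]
        assert (case["sex"] == "M").sum() == 47 and (case["sex"] == "F").sum() == 12
        assert (ctrl["sex"] == "M").sum() == 58 and (ctrl["sex"] == "F").sum() == 11

    def test_same_seed_reproduces_table(self):
        a = generate_cohort(seed=5)
        b = generate_cohort(seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_scale_means_near_configured_values(self):
        # large cohort: sample moments converge to the configured values
        cfg = CohortConfig().resized(5000, 5000)
        demo = generate_cohort(cfg, seed=3)
        case = demo[demo["group"] == CASE]
        for name, p in cfg.scale_params.items():
            se = p.case_sd / np.sqrt(len(case))
            assert abs(case[name].mean() - p.case_mean) < 4 * se
            assert abs(case[name].std(ddof=1) - p.case_sd) / p.case_sd < 0.05

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(n_case=1)
        with pytest.raises(ValueError):
            CohortConfig(case_sex_counts=(50, 10))


class TestFeatureTable:
    def test_columns_follow_schema_order(self, small_schema, small_table):
        assert small_table.feature_ids == small_schema.feature_ids

    def test_planted_group_means_match_published_values(self, small_schema, cohort):
        # seed-averaged check of the internal-capsule MD dispersion feature
        fid = "white.left.anterior_limb_of_internal_capsule.md.std"
        spec = next(e for e in DEFAULT_EFFECTS if e.feature_id == fid)
        for seed in (0, 1, 2):
            t = generate_feature_table(small_schema, cohort["group"], seed=seed)
            col = t.data[fid]
            case = col[t.labels == CASE]
            ctrl = col[t.labels == CONTROL]
            assert abs(case.mean() - spec.case_mean) < 3 * spec.case_sd / np.sqrt(len(case))
            assert abs(ctrl.mean() - spec.control_mean) < 3 * spec.control_sd / np.sqrt(len(ctrl))

    def test_null_features_show_no_systematic_group_difference(self, small_schema, cohort):
        # direct t-test sweep: no null feature should clear Bonferroni in
        # nearly all seeded generations
        labels = cohort["group"]
        is_case = (labels == CASE).to_numpy()
        planted = {e.feature_id for e in DEFAULT_EFFECTS}
        n_bad_runs = 0
        runs = 20
        for seed in range(runs):
            t = generate_feature_table(small_schema, labels, seed=seed)
            null_cols = [c for c in t.feature_ids if c not in planted]
            X = t.data[null_cols].to_numpy()
            res = sps.ttest_ind(X[is_case], X[~is_case], axis=0)
            if (res.pvalue < 0.05 / len(null_cols)).any():
                n_bad_runs += 1
        assert n_bad_runs <= 1  # >=95% of runs clean

    def test_extreme_effect_gives_extreme_t(self, small_schema, cohort):
        # closed form: E[t] ~ delta / (sigma sqrt(1/n1 + 1/n2)) ~ 56 at d=10
        fid = small_schema.feature_ids[0]
        eff = (EffectSpec(fid, 10.0, 1.0, 0.0, 1.0),)
        t = generate_feature_table(small_schema, cohort["group"], effects=eff, seed=4)
        col = t.data[fid]
        res = sps.ttest_ind(col[t.labels == CASE], col[t.labels == CONTROL])
        assert abs(res.statistic) > 10

    def test_moment_recovery_at_large_n(self):
        # planted per-group moments converge within 1% at n=10,000
        cfg = SchemaConfig(
            cortical_regions=("cuneus",), tract_labels=(), subcortical_structures=(),
            include_volumes=False,
        )
        schema = build_default_schema(cfg)
        labels = pd.Series(
            [CASE] * 10_000 + [CONTROL] * 10_000,
            index=pd.Index(range(20_000), name="subject_id"), name="group",
        )
        fid = "gray.left.cuneus.local_thickness.mean"
        eff = (EffectSpec(fid, 1.99, 0.17, 1.88, 0.16),)
        t = generate_feature_table(schema, labels, effects=eff, seed=9)
        case = t.data.loc[labels == CASE, fid]
        assert abs(case.mean() - 1.99) / 1.99 < 0.01
        assert abs(case.std(ddof=1) - 0.17) / 0.17 < 0.05

    def test_block_correlation_structure(self, cohort):
        cfg = SchemaConfig(
            cortical_regions=("cuneus", "lingual"), tract_labels=(),
            subcortical_structures=(), include_volumes=False,
        )
        schema = build_default_schema(cfg)
        noise = NoiseConfig(block_size=8, within_block_corr=0.5)
        t = generate_feature_table(schema, cohort["group"], effects=(), noise=noise, seed=7)
        C = np.corrcoef(t.data.to_numpy(), rowvar=False)
        within = C[:8, :8][np.triu_indices(8, 1)]
        across = C[:8, 8:16].ravel()
        assert within.mean() > 0.35
        assert abs(across.mean()) < 0.15

    def test_unknown_effect_feature_raises(self, small_schema, cohort):
        with pytest.raises(KeyError, match="bogus"):
            generate_feature_table(
                small_schema, cohort["group"],
                effects=(EffectSpec("bogus", 1, 1, 0, 1),),
            )

    def test_same_seed_identical_tables(self, small_schema, cohort):
        a = generate_feature_table(small_schema, cohort["group"], seed=42)
        b = generate_feature_table(small_schema, cohort["group"], seed=42)
        pd.testing.assert_frame_equal(a.data, b.data)


class TestPermutations:
    def test_permutation_preserves_group_sizes(self, cohort):
        perms = permute_labels(cohort["group"], 10, seed=1)
        assert len(perms) == 10
        for p in perms:
            assert (p == CASE).sum() == 59
            assert (p == CONTROL).sum() == 69

    def test_requested_count_produced(self, cohort):
        assert len(permute_labels(cohort["group"], 1000, seed=0)) == 1000

    def test_seeded_sequence_reproducible(self, cohort):
        a = permute_labels(cohort["group"], 5, seed=9)
        b = permute_labels(cohort["group"], 5, seed=9)
        for pa, pb in zip(a, b):
            assert (pa == pb).all()

    def test_invalid_count_rejected(self, cohort):
        with pytest.raises(ValueError):
            permute_labels(cohort["group"], 0)
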