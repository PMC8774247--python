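"""Repeated stratified k-fold harness, confusion metrics, selection frequency."""

import numpy as np
import pandas as pd
import pytest

from radsel.boruta import RFConfig
from radsel.cv import (
    ConfusionMatrix,
    CVConfig,
    SelectionRecord,
    confusion_metrics,
    make_partitions,
    run_nested_cv,
    selection_frequency,
)

from conftest import make_toy_table

FAST_RF = RFConfig(n_trees=50)


class TestPartitions:
    def test_fold_sizes_differ_by_at_most_one(self, cohort):
        parts = make_partitions(cohort["group"], CVConfig(k=5, repeats=3), seed=0)
        for folds in parts:
            sizes = sorted(len(f) for f in folds)
            assert sizes == [25, 25, 26, 26, 26]  # 128 subjects into 5 folds

    def test_folds_partition_all_subjects(self, cohort):
        parts = make_partitions(cohort["group"], CVConfig(k=5, repeats=2), seed=1)
        n = len(cohort)
        for folds in parts:
            all_idx = np.concatenate(folds)
            assert sorted(all_idx) == list(range(n))

    def test_stratification_keeps_group_balance(self, cohort):
        y = cohort["group"].to_numpy()
        parts = make_partitions(y, CVConfig(k=5, repeats=2), seed=2)
        global_rate = (y == "case").mean()
        for folds in parts:
            for fold in folds:
                rate = (y[fold] == "case").mean()
                assert abs(rate - global_rate) <= 1 / len(fold) + 1e-9

    def test_total_iteration_count(self, cohort):
        cfg = CVConfig(k=5, repeats=100)
        assert cfg.n_iterations == 500
        parts = make_partitions(cohort["group"], CVConfig(k=5, repeats=4), seed=3)
        assert sum(len(folds) for folds in parts) == 20

    def test_group_smaller_than_k_rejected(self):
        y = np.array(["case"] * 3 + ["control"] * 20)
        with pytest.raises(ValueError):
            make_partitions(y, CVConfig(k=5, repeats=1), seed=0)

    def test_deterministic_under_seed(self, cohort):
        a = make_partitions(cohort["group"], CVConfig(k=5, repeats=2), seed=5)
        b = make_partitions(cohort["group"], CVConfig(k=5, repeats=2), seed=5)
        for fa, fb in zip(a, b):
            for x, y_ in zip(fa, fb):
                assert (x == y_).all()


class TestConfusionMetrics:
    @pytest.mark.parametrize(
        "cm,expected",
        [
            (ConfusionMatrix(10, 0, 10, 0), {"accuracy": 1.0, "kappa": 1.0}),
            (ConfusionMatrix(8, 3, 7, 2), {"accuracy": 0.75, "kappa": 0.5}),
            (ConfusionMatrix(0, 10, 0, 10), {"accuracy": 0.0, "kappa": -1.0}),
        ],
    )
    def test_reference_values(self, cm, expected):
        out = confusion_metrics(cm)
        for key, val in expected.items():
            assert out[key] == pytest.approx(val)

    def test_agrees_with_brute_force_recount(self):
        # oracle: recompute every metric from raw (truth, prediction) pairs
        rng = np.random.default_rng(0)
        for _ in range(1000):
            n = int(rng.integers(2, 30))
            truth = rng.integers(0, 2, n)
            pred = rng.integers(0, 2, n)
            cm = ConfusionMatrix(
                tp=int(((pred == 1) & (truth == 1)).sum()),
                fp=int(((pred == 1) & (truth == 0)).sum()),
                tn=int(((pred == 0) & (truth == 0)).sum()),
                fn=int(((pred == 0) & (truth == 1)).sum()),
            )
            out = confusion_metrics(cm)
            assert out["accuracy"] == pytest.approx((pred == truth).mean())
            po = (pred == truth).mean()
            pe = (truth == 1).mean() * (pred == 1).mean() + (truth == 0).mean() * (pred == 0).mean()
            if pe < 1:
                assert out["kappa"] == pytest.approx((po - pe) / (1 - pe))
            if (truth == 1).any():
                assert out["sensitivity"] == pytest.approx(pred[truth == 1].mean())

    def test_undefined_ratio_reported_as_nan(self):
        out = confusion_metrics(ConfusionMatrix(tp=0, fp=0, tn=5, fn=0))
        assert np.isnan(out["sensitivity"])
        assert out["specificity"] == 1.0


class TestSelectionFrequency:
    def test_reference_fractions(self):
        ids = ["a", "b", "c"]
        records = [
            SelectionRecord(i, frozenset(["a"]) if i <= 498 else frozenset())
            for i in range(1, 501)
        ]
        freqs = selection_frequency(records, ids, 500)
        assert freqs["a"] == pytest.approx(0.996)  # 498 of 500
        assert freqs["b"] == 0.0
        half = [SelectionRecord(i, frozenset(["c"]) if i <= 250 else frozenset())
                for i in range(1, 501)]
        assert selection_frequency(half, ids, 500)["c"] == pytest.approx(0.5)

    def test_count_mismatch_rejected(self):
        with pytest.raises(ValueError):
            selection_frequency([SelectionRecord(1, frozenset())], ["a"], 2)

    def test_unknown_feature_in_record_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            selection_frequency([SelectionRecord(1, frozenset(["zz"]))], ["a"], 1)


class TestNestedCV:
    def test_near_separable_feature_yields_high_accuracy(self):
        # Bayes error of two unit-variance Gaussians at d=6 is ~0.0013
        t = make_toy_table(n_case=40, n_control=40, n_features=10, d=6.0, seed=0)
        res = run_nested_cv(t, cv=CVConfig(k=5, repeats=2), rf=FAST_RF,
                            max_iter=25, seed=0)
        assert res.summary.mean["accuracy"] > 0.95
        assert res.n_iterations == 10

    def test_null_data_stays_in_chance_band(self):
        t = make_toy_table(n_case=32, n_control=32, n_features=15, seed=1)
        res = run_nested_cv(t, cv=CVConfig(k=5, repeats=1), rf=FAST_RF,
                            max_iter=20, seed=1)
        assert 0.35 <= res.summary.mean["accuracy"] <= 0.65
        assert -0.2 <= res.summary.mean["kappa"] <= 0.2

    def test_empty_selection_iterations_are_flagged_not_fatal(self):
        t = make_toy_table(n_case=20, n_control=20, n_features=8, seed=2)
        res = run_nested_cv(t, cv=CVConfig(k=4, repeats=1), rf=FAST_RF,
                            max_iter=20, seed=2)
        # pure-null data: most iterations confirm nothing yet all are recorded
        assert len(res.records) == 4
        assert any(r.empty_selection for r in res.records)

    def test_deterministic_under_seed(self):
        t = make_toy_table(n_case=24, n_control=24, n_features=8, d=2.0, seed=3)
        a = run_nested_cv(t, cv=CVConfig(k=4, repeats=1), rf=FAST_RF, max_iter=10, seed=9)
        b = run_nested_cv(t, cv=CVConfig(k=4, repeats=1), rf=FAST_RF, max_iter=10, seed=9)
        assert a.summary.mean == b.summary.mean
        assert [r.selected for r in a.records] == [r.selected for r in b.records]

    def test_metric_ranges_and_sds(self):
        t = make_toy_table(n_case=30, n_control=30, n_features=10, d=2.0, seed=4)
        res = run_nested_cv(t, cv=CVConfig(k=5, repeats=1), rf=FAST_RF, max_iter=15, seed=4)
        for m in ("accuracy", "sensitivity", "specificity"):
            assert 0.0 <= res.summary.mean[m] <= 1.0
        assert -1.0 <= res.summary.mean["kappa"] <= 1.0
        assert all(sd >= 0 or np.isnan(sd) for sd in res.summary.sd.values())
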