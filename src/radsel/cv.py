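"""Repeated k-fold cross-validation with selection embedded in training folds.

Each of the ``repeats`` x ``k`` iterations runs the all-relevant selector
on the training folds only, trains a random forest on the selected
features (mtry = floor(sqrt(p_selected))), predicts the held-out fold, and
records the confusion matrix and the selected feature set.  Performance
(accuracy, Cohen's kappa, sensitivity, specificity; case = positive class)
is aggregated as mean +/- SD over all iterations; selected sets aggregate
into per-feature selection frequencies, the statistic tested downstream.

Folds are stratified by default: with a 59/69 group imbalance plain random
k-folds occasionally produce near-degenerate test folds.  Iterations whose
selector confirms nothing predict the training-fold majority class, so the
iteration count stays intact on null data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold, StratifiedKFold

from .boruta import RFConfig, boruta_select
from .tables import CASE, FeatureTable

__all__ = [
    "CVConfig",
    "ConfusionMatrix",
    "MetricSummary",
    "SelectionRecord",
    "CVResult",
    "make_partitions",
    "run_nested_cv",
    "confusion_metrics",
    "selection_frequency",
]


@dataclass(frozen=True)
class CVConfig:
    k: int = 5
    repeats: int = 100
    stratified: bool = True

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")

    @property
    def n_iterations(self) -> int:
        return self.k * self.repeats


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class SelectionRecord:
    iteration: int
    selected: frozenset[str]
    empty_selection: bool = False


@dataclass
class MetricSummary:
    """Mean +/- SD of each metric over all CV iterations (NaN-aware: an
    iteration with an undefined ratio is excluded from that metric only)."""

    mean: dict[str, float]
    sd: dict[str, float]
    n_iterations: int

    @classmethod
    def from_per_iteration(cls, per_iter: pd.DataFrame) -> "MetricSummary":
        return cls(
            mean={c: float(np.nanmean(per_iter[c])) for c in per_iter.columns},
            sd={c: float(np.nanstd(per_iter[c], ddof=1)) for c in per_iter.columns},
            n_iterations=len(per_iter),
        )


@dataclass
class CVResult:
    summary: MetricSummary
    per_iteration: pd.DataFrame = field(repr=False)
    records: list[SelectionRecord] = field(repr=False)

    @property
    def n_iterations(self) -> int:
        return len(self.records)


def make_partitions(
    labels, cv: CVConfig, seed: int | np.random.Generator = 0
) -> list[list[np.ndarray]]:
    """Per-repeat lists of k disjoint test-fold index arrays.

    Folds cover all subjects, sizes differ by at most one; stratified folds
    keep per-fold group proportions within one subject of the global split.
    """
    y = np.asarray(labels)
    rng = np.random.default_rng(seed)
    classes, counts = np.unique(y, return_counts=True)
    if cv.stratified and counts.min() < cv.k:
        raise ValueError(
            f"smallest group ({counts.min()}) has fewer members than k={cv.k}"
        )
    partitions = []
    for _ in range(cv.repeats):
        state = int(rng.integers(2**31 - 1))
        splitter = (
            StratifiedKFold(cv.k, shuffle=True, random_state=state)
            if cv.stratified
            else KFold(cv.k, shuffle=True, random_state=state)
        )
        partitions.append([test for _, test in splitter.split(np.zeros(len(y)), y)])
    return partitions


def confusion_metrics(m: ConfusionMatrix) -> dict[str, float]:
    """accuracy, sensitivity (case positive), specificity, Cohen's kappa.

    Undefined ratios (zero denominators) come back as NaN.
    """
    n = m.total
    if n == 0:
        raise ValueError("empty confusion matrix")
    acc = (m.tp + m.tn) / n
    sens = m.tp / (m.tp + m.fn) if (m.tp + m.fn) else np.nan
    spec = m.tn / (m.tn + m.fp) if (m.tn + m.fp) else np.nan
    # chance agreement from marginal products
    p_yes = ((m.tp + m.fn) / n) * ((m.tp + m.fp) / n)
    p_no = ((m.tn + m.fp) / n) * ((m.tn + m.fn) / n)
    pe = p_yes + p_no
    kappa = (acc - pe) / (1 - pe) if pe < 1 else np.nan
    return {"accuracy": acc, "kappa": kappa, "sensitivity": sens, "specificity": spec}


def selection_frequency(
    records: list[SelectionRecord], feature_ids: list[str], n_iterations: int
) -> pd.Series:
    """Per-feature fraction of iterations in which the feature was selected.

    Features never selected get frequency 0; every id in ``feature_ids`` is
    reported.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    if len(records) != n_iterations:
        raise ValueError(
            f"record count {len(records)} does not match n_iterations {n_iterations}"
        )
    counts = pd.Series(0, index=pd.Index(feature_ids, name="feature_id"), dtype=float)
    for rec in records:
        extra = rec.selected - set(feature_ids)
        if extra:
            raise ValueError(f"records mention unknown features: {sorted(extra)[:3]}")
        counts[list(rec.selected)] += 1
    return counts / n_iterations


def run_nested_cv(
    table: FeatureTable,
    cv: CVConfig | None = None,
    rf: RFConfig | None = None,
    max_iter: int = 100,
    selector_alpha: float = 0.01,
    seed: int | np.random.Generator = 0,
    positive: str = CASE,
) -> CVResult:
    """Run the full selection-inside-CV loop on an (already screened) table."""
    cv = cv or CVConfig()
    rf = rf or RFConfig()
    rng = np.random.default_rng(seed)

    y = table.labels.to_numpy()
    ybin = table.y(positive)
    X = table.data
    feature_ids = table.feature_ids

    partitions = make_partitions(y, cv, rng)
    rows, records = [], []
    iteration = 0
    for folds in partitions:
        for test_idx in folds:
            iteration += 1
            train_mask = np.ones(len(y), dtype=bool)
            train_mask[test_idx] = False
            if len(np.unique(y[test_idx])) < 2 or len(np.unique(y[train_mask])) < 2:
                raise ValueError(f"iteration {iteration}: single-class fold")

            Xtr, ytr = X.iloc[train_mask.nonzero()[0]], ybin[train_mask]
            Xte, yte = X.iloc[test_idx], ybin[test_idx]

            sel = boruta_select(
                Xtr, ytr, rf=rf, max_iter=max_iter, alpha=selector_alpha, seed=rng
            )
            chosen = sel.selected
            empty = len(chosen) == 0
            if empty:
                majority = int(np.round(ytr.mean()))  # training-fold majority class
                pred = np.full(len(yte), majority)
            else:
                forest = rf.make_forest(len(chosen), rng)
                forest.fit(Xtr.loc[:, chosen], ytr)
                pred = forest.predict(Xte.loc[:, chosen])

            cm = ConfusionMatrix(
                tp=int(np.sum((pred == 1) & (yte == 1))),
                fp=int(np.sum((pred == 1) & (yte == 0))),
                tn=int(np.sum((pred == 0) & (yte == 0))),
                fn=int(np.sum((pred == 0) & (yte == 1))),
            )
            rows.append(confusion_metrics(cm))
            records.append(
                SelectionRecord(iteration, frozenset(chosen), empty_selection=empty)
            )

    per_iteration = pd.DataFrame(rows, index=pd.RangeIndex(1, iteration + 1, name="iteration"))
    return CVResult(MetricSummary.from_per_iteration(per_iteration), per_iteration, records)
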