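"""Coarse univariate screen applied before all-relevant selection.

Features are z-scored over the full table and then filtered by a one-way
ANOVA per feature (uncorrected p < alpha keeps the feature).  For two
groups the F statistic equals the square of the pooled two-sample t, which
the implementation exploits and the test suite verifies.

Z-scoring over the full table (rather than per training fold) reproduces
the workflow this package models; it leaks the held-out fold's scale into
training.  ``zscore_per_fold`` is provided for leak-free variants.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .tables import FeatureTable

__all__ = ["ScreenResult", "zscore_normalize", "anova_filter"]


@dataclass
class ScreenResult:
    """Per-feature screen statistics and the surviving feature ids."""

    kept_ids: list[str]
    per_feature: pd.DataFrame   # index: feature id; columns: F, p_value, kept, constant
    alpha: float

    @property
    def n_kept(self) -> int:
        return len(self.kept_ids)


def zscore_normalize(table: FeatureTable) -> tuple[FeatureTable, list[str]]:
    """Scale every feature to mean 0, sample SD 1 (ddof=1).

    Constant columns cannot be scaled; they come back as all-zero and their
    ids are returned as flags.
    """
    X = table.data
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    constant = sd[sd == 0].index.tolist()
    sd_safe = sd.replace(0, 1.0)
    Z = (X - mu) / sd_safe
    return FeatureTable(Z, table.labels), constant


def _two_group_f(X: np.ndarray, is_a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized pooled-t-squared F for a two-group comparison, per column."""
    n1, n2 = int(is_a.sum()), int((~is_a).sum())
    a, b = X[is_a], X[~is_a]
    m1, m2 = a.mean(axis=0), b.mean(axis=0)
    v1, v2 = a.var(axis=0, ddof=1), b.var(axis=0, ddof=1)
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t2 = (m1 - m2) ** 2 / (sp2 * (1 / n1 + 1 / n2))
    df2 = n1 + n2 - 2
    p = sps.f.sf(t2, 1, df2)
    return t2, p


def anova_filter(table: FeatureTable, alpha: float = 0.05) -> ScreenResult:
    """One-way ANOVA per feature; keep features with uncorrected p < alpha.

    Constant features (zero variance overall) are excluded and recorded
    with undefined F.  A feature identical in both groups has F = 0 and is
    excluded at any alpha < 1.
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must lie in (0, 1]")
    groups = table.groups
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 groups, got {groups}")
    y = table.labels.to_numpy()
    is_a = y == groups[0]
    if is_a.sum() < 2 or (~is_a).sum() < 2:
        raise ValueError("each group needs n >= 2")

    X = table.data.to_numpy(dtype=float)
    F, p = _two_group_f(X, is_a)
    constant = X.std(axis=0, ddof=1) == 0
    F = np.where(constant, np.nan, F)
    p = np.where(constant, np.nan, p)
    kept = ~constant & (p < alpha)

    per_feature = pd.DataFrame(
        {"F": F, "p_value": p, "kept": kept, "constant": constant},
        index=pd.Index(table.feature_ids, name="feature_id"),
    )
    kept_ids = [fid for fid, k in zip(table.feature_ids, kept) if k]
    return ScreenResult(kept_ids, per_feature, alpha)
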