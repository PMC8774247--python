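"""Significance of selection frequency via a permutation-calibrated binomial null.

A feature selected in k of M cross-validation iterations is tested against
X ~ Binomial(M, p0), where p0 — the chance rate of being selected in one
iteration — is estimated as the mean selection frequency pooled over all
features of label-permuted datasets run through the identical
selection-inside-CV pipeline.  Upper-tail p-values are Bonferroni-adjusted
over the family of features that entered selection, and features selected
in fewer than half the iterations on the original data are excluded
regardless of p-value (the minimum-frequency floor).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .boruta import RFConfig
from .cv import CVConfig, run_nested_cv, selection_frequency
from .simulate import permute_labels
from .tables import FeatureTable

__all__ = [
    "NullModel",
    "SignificanceReport",
    "estimate_null_rate",
    "binomial_tail_p",
    "significant_features",
    "run_permutation_calibration",
]


@dataclass
class NullModel:
    """Estimated chance selection rate and its provenance."""

    p0: float
    n_iterations: int                 # M of the *original* run the null applies to
    n_permutations: int
    per_permutation_mean_freq: list[float] = field(default_factory=list)
    degenerate: bool = False          # p0 == 0: downstream p-values are 0/1 indicators


def estimate_null_rate(
    permutation_freqs: list[pd.Series], n_iterations: int
) -> NullModel:
    """Pool per-feature selection frequencies over permuted datasets.

    ``p0`` is the grand mean over all features and all permutations (one
    global rate, not per-feature); per-permutation means are kept for
    diagnostics.
    """
    if not permutation_freqs:
        raise ValueError("need at least one permutation's frequencies")
    # a permutation whose screened family came up empty contributes nothing
    per_perm = [float(np.mean(f)) if len(f) else 0.0 for f in permutation_freqs]
    values = [np.asarray(f, dtype=float) for f in permutation_freqs if len(f)]
    pooled = float(np.mean(np.concatenate(values))) if values else 0.0
    return NullModel(
        p0=pooled,
        n_iterations=n_iterations,
        n_permutations=len(permutation_freqs),
        per_permutation_mean_freq=per_perm,
        degenerate=pooled == 0.0,
    )


def binomial_tail_p(k: int, M: int, p0: float) -> float:
    """Upper-tail P(X >= k) for X ~ Binomial(M, p0).

    Uses the survival function (numerically stable in the far tail);
    k = 0 covers the whole support and returns 1.
    """
    if not 0 <= k <= M:
        raise ValueError(f"k={k} outside [0, M={M}]")
    if not 0.0 <= p0 <= 1.0:
        raise ValueError(f"p0={p0} outside [0, 1]")
    if k == 0:
        return 1.0
    return float(sps.binom.sf(k - 1, M, p0))


@dataclass
class SignificanceReport:
    """Per-feature selection-frequency test, sorted by descending frequency."""

    table: pd.DataFrame   # observed_freq, hits, raw_p, adjusted_p, passes_min_freq, significant
    alpha: float
    min_freq: float
    n_tests: int

    @property
    def significant_ids(self) -> list[str]:
        return self.table.index[self.table["significant"]].tolist()


def significant_features(
    freqs: pd.Series,
    null: NullModel,
    alpha: float = 0.05,
    min_freq: float = 0.5,
    n_tests: int | None = None,
) -> SignificanceReport:
    """Test each feature's observed selection frequency against the null.

    raw p = P(X >= k | Binomial(M, p0)) with k = round(freq * M);
    adjusted p = min(1, raw p * n_tests) (Bonferroni over the features that
    entered selection); significant iff adjusted p < alpha AND the observed
    frequency clears the half-of-iterations floor.
    """
    if not 0.0 <= min_freq <= 1.0:
        raise ValueError("min_freq must lie in [0, 1]")
    M = null.n_iterations
    n_tests = len(freqs) if n_tests is None else n_tests

    hits = np.rint(np.asarray(freqs, dtype=float) * M).astype(int)
    raw = np.array([binomial_tail_p(int(k), M, null.p0) for k in hits])
    adjusted = np.minimum(1.0, raw * n_tests)
    passes = np.asarray(freqs, dtype=float) >= min_freq
    significant = (adjusted < alpha) & passes

    out = pd.DataFrame(
        {
            "observed_freq": np.asarray(freqs, dtype=float),
            "hits": hits,
            "raw_p": raw,
            "adjusted_p": adjusted,
            "passes_min_freq": passes,
            "significant": significant,
        },
        index=freqs.index,
    ).sort_values("observed_freq", ascending=False, kind="stable")
    return SignificanceReport(out, alpha, min_freq, n_tests)


def run_permutation_calibration(
    table: FeatureTable,
    n_perm: int,
    cv: CVConfig | None = None,
    rf: RFConfig | None = None,
    max_iter: int = 100,
    selector_alpha: float = 0.01,
    screen_alpha: float | None = None,
    seed: int | np.random.Generator = 0,
) -> NullModel:
    """Estimate p0 by rerunning the full pipeline on label-permuted copies.

    Each permuted dataset is processed exactly like the original: when
    ``screen_alpha`` is given, the univariate screen is redone under the
    permuted labels and selection runs on that permutation's own
    survivors.  This keeps the null runs' leakage structure identical to
    the original run's (the screen sees the full table there too), so the
    pooled mean frequency estimates the chance selection rate of *a
    feature that entered selection*.  With ``screen_alpha=None`` the table
    is used as-is (already screened upstream, or no screening wanted).

    Classification metrics of permuted runs are discarded; ``cv`` may be a
    reduced desk-scale configuration — p0 is a per-iteration rate, so the
    caller applies it to the original run's own iteration count.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    cv = cv or CVConfig()
    rf = rf or RFConfig()
    rng = np.random.default_rng(seed)

    from .screening import anova_filter  # local import: avoids a cycle

    perms = permute_labels(table.labels, n_perm, rng)
    freqs = []
    for perm in perms:
        permuted = table.with_labels(perm)
        if screen_alpha is not None:
            kept = anova_filter(permuted, alpha=screen_alpha).kept_ids
            if not kept:
                freqs.append(pd.Series(dtype=float))  # empty family this draw
                continue
            permuted = permuted.subset_features(kept)
        res = run_nested_cv(
            permuted, cv=cv, rf=rf, max_iter=max_iter,
            selector_alpha=selector_alpha, seed=rng,
        )
        freqs.append(
            selection_frequency(res.records, permuted.feature_ids, cv.n_iterations)
        )
    return estimate_null_rate(freqs, cv.n_iterations)
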