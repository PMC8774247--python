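"""Demographic/clinical group comparisons and diagnostic classification rules.

Implements the comparisons used for the cohort description tables: pooled
two-sample t (from raw data or from printed summary statistics), a
normality-gated raw comparison that falls back to Mann-Whitney U, Pearson
chi-square for sex, plus the two screening-instrument rules (the 8-item
yes/no internet-addiction questionnaire and the 26-item severity scale
with its 63/64 cutoff).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .tables import GROUP_COLUMN

__all__ = [
    "GroupSummary",
    "TestResult",
    "pooled_t_from_summary",
    "compare_groups_raw",
    "chi2_independence",
    "ydq_classify",
    "cias_classify",
    "summarize_demographics",
]


@dataclass(frozen=True)
class GroupSummary:
    """n, mean and sample SD of one group on one variable."""

    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("group summary needs n >= 2")
        if self.sd < 0:
            raise ValueError("sd must be nonnegative")

    @classmethod
    def from_sample(cls, x) -> "GroupSummary":
        x = np.asarray(x, dtype=float)
        return cls(len(x), float(np.mean(x)), float(np.std(x, ddof=1)))


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float | None
    p_value: float
    test_name: str      # pooled_t | mann_whitney | chi2 | ks
    flag: str | None = None


def pooled_t_from_summary(a: GroupSummary, b: GroupSummary) -> TestResult:
    """Student pooled-variance two-sample t from summary statistics.

    sp^2 = ((n1-1)s1^2 + (n2-1)s2^2)/(n1+n2-2); t = (m1-m2)/(sp sqrt(1/n1+1/n2));
    df = n1+n2-2; two-sided p.
    """
    df = a.n + b.n - 2
    sp2 = ((a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2) / df
    if sp2 == 0:
        if a.mean == b.mean:
            raise ZeroDivisionError("degenerate comparison: zero variance, equal means")
        return TestResult(np.inf if a.mean > b.mean else -np.inf, df, 0.0, "pooled_t")
    t = (a.mean - b.mean) / np.sqrt(sp2 * (1 / a.n + 1 / b.n))
    p = 2 * sps.t.sf(abs(t), df)
    return TestResult(float(t), float(df), float(p), "pooled_t")


def _ks_normality_p(x: np.ndarray) -> float:
    # One-sample KS against N(sample mean, sample SD) — the common applied
    # usage of the KS normality check (not Lilliefors-corrected).
    return float(sps.kstest(x, "norm", args=(np.mean(x), np.std(x, ddof=1))).pvalue)


def compare_groups_raw(x, y, normality_alpha: float = 0.05) -> TestResult:
    """Compare two raw samples: pooled t if both pass a KS normality gate,
    otherwise two-sided Mann-Whitney U (normal approximation, tie-corrected)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(y) < 3:
        raise ValueError("each sample needs n >= 3")

    sx, sy = np.std(x, ddof=1), np.std(y, ddof=1)
    normal = (
        sx > 0 and sy > 0
        and _ks_normality_p(x) > normality_alpha
        and _ks_normality_p(y) > normality_alpha
    )
    if normal:
        return pooled_t_from_summary(GroupSummary.from_sample(x), GroupSummary.from_sample(y))
    if sx == 0 and sy == 0 and x[0] == y[0]:
        return TestResult(0.0, None, 1.0, "mann_whitney", flag="all_ties")
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return TestResult(float(res.statistic), None, float(res.pvalue), "mann_whitney")


def chi2_independence(counts) -> TestResult:
    """Pearson chi-square on a 2x2 table, no continuity correction, df=1."""
    table = np.asarray(counts, dtype=float)
    if table.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("zero row or column margin")
    chi2, p, df, _ = sps.chi2_contingency(table, correction=False)
    return TestResult(float(chi2), float(df), float(p), "chi2")


def ydq_classify(answers: Sequence[bool]) -> bool:
    """8-item yes/no internet-addiction rule: items 1-5 all yes, plus at
    least one of items 6-8."""
    if len(answers) != 8:
        raise ValueError("expected exactly 8 answers")
    answers = [bool(a) for a in answers]
    return all(answers[:5]) and any(answers[5:])


def cias_classify(score: float, cutoff: float = 63.5) -> bool:
    """Severity-scale rule: positive above the 63/64 boundary.

    Scores live on [26, 104] (26 items, four-point scale)."""
    if not 26 <= score <= 104:
        raise ValueError(f"score {score} outside the 26-104 scale range")
    return score > cutoff


def summarize_demographics(
    demographics: pd.DataFrame, normality_alpha: float = 0.05
) -> pd.DataFrame:
    """Cohort-description report: per-scale group means +/- SD and the
    group-comparison statistic; sex via chi-square.

    Expects the layout written by :func:`radsel.simulate.generate_cohort`
    (a ``group`` column, an optional ``sex`` column, numeric scale columns).
    """
    if GROUP_COLUMN not in demographics.columns:
        raise ValueError(f"demographics table needs a {GROUP_COLUMN!r} column")
    groups = sorted(demographics[GROUP_COLUMN].unique())
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 groups, got {groups}")
    g1, g2 = demographics[GROUP_COLUMN] == groups[0], demographics[GROUP_COLUMN] == groups[1]

    rows = []
    if "sex" in demographics.columns:
        tab = pd.crosstab(demographics[GROUP_COLUMN], demographics["sex"])
        res = chi2_independence(tab.to_numpy())
        rows.append({"variable": "sex", "test": res.test_name,
                     f"{groups[0]}_summary": "/".join(map(str, tab.loc[groups[0]])),
                     f"{groups[1]}_summary": "/".join(map(str, tab.loc[groups[1]])),
                     "statistic": res.statistic, "df": res.df, "p_value": res.p_value})

    numeric = demographics.select_dtypes("number").columns
    for col in numeric:
        x = demographics.loc[g1, col].to_numpy(dtype=float)
        y = demographics.loc[g2, col].to_numpy(dtype=float)
        res = compare_groups_raw(x, y, normality_alpha)
        rows.append({"variable": col, "test": res.test_name,
                     f"{groups[0]}_summary": f"{np.mean(x):.2f} ± {np.std(x, ddof=1):.2f}",
                     f"{groups[1]}_summary": f"{np.mean(y):.2f} ± {np.std(y, ddof=1):.2f}",
                     "statistic": res.statistic, "df": res.df, "p_value": res.p_value})
    return pd.DataFrame(rows)
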