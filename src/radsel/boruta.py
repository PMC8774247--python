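"""All-relevant feature selection with shadow features (Boruta-style).

The selector decides, for every feature, whether it carries *any*
information about the class label — as opposed to minimal-optimal methods
that hunt for one small predictive subset.  Each iteration appends an
independently shuffled "shadow" copy of every still-undecided feature,
fits a random forest on the extended matrix, and scores a real feature a
"hit" when its importance strictly exceeds the best shadow importance of
that iteration.  Cumulative hit counts are then tested against
Binomial(iterations, 1/2): a significantly high count confirms the
feature, a significantly low count rejects it.  Features undecided when
the iteration budget runs out are tentative and are *not* selected.

The forest follows the convention of the modeled workflow: ``n_trees``
trees (default 1000) and mtry = floor(sqrt(p)) candidate features per
split.  Importance is the forest's impurity-based measure by default, with
scikit-learn permutation importance as an option.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance

__all__ = ["RFConfig", "BorutaResult", "boruta_select"]

CONFIRMED = "confirmed"
REJECTED = "rejected"
TENTATIVE = "tentative"


@dataclass(frozen=True)
class RFConfig:
    """Random-forest settings shared by the selector and the classifier."""

    n_trees: int = 1000
    mtry_rule: str = "sqrt"     # mtry = floor(sqrt(p))
    importance: str = "impurity"  # or "permutation"

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.mtry_rule != "sqrt":
            raise ValueError(f"unsupported mtry rule {self.mtry_rule!r}")
        if self.importance not in ("impurity", "permutation"):
            raise ValueError(f"unknown importance measure {self.importance!r}")

    def make_forest(self, n_features: int, seed) -> RandomForestClassifier:
        return RandomForestClassifier(
            n_estimators=self.n_trees,
            max_features=max(1, int(np.floor(np.sqrt(n_features)))),
            random_state=_as_int_seed(seed),
            n_jobs=1,
        )


def _as_int_seed(seed) -> int:
    if isinstance(seed, np.random.Generator):
        return int(seed.integers(2**31 - 1))
    return int(seed)


@dataclass
class BorutaResult:
    """Outcome of one selection run."""

    feature_ids: list[str]
    decisions: dict[str, str]            # feature id -> confirmed/rejected/tentative
    hit_counts: dict[str, int]
    n_iterations_run: int
    importance_history: list[dict] = field(repr=False, default_factory=list)

    @property
    def confirmed(self) -> list[str]:
        return [f for f in self.feature_ids if self.decisions[f] == CONFIRMED]

    @property
    def rejected(self) -> list[str]:
        return [f for f in self.feature_ids if self.decisions[f] == REJECTED]

    @property
    def tentative(self) -> list[str]:
        return [f for f in self.feature_ids if self.decisions[f] == TENTATIVE]

    @property
    def selected(self) -> list[str]:
        """The selected set: confirmed features only (tentative excluded)."""
        return self.confirmed


def _importances(forest, X, y, cfg: RFConfig, rng) -> np.ndarray:
    if cfg.importance == "impurity":
        return forest.feature_importances_
    res = permutation_importance(
        forest, X, y, n_repeats=5, random_state=_as_int_seed(rng), n_jobs=1
    )
    return res.importances_mean


def boruta_select(
    X,
    y,
    feature_ids: list[str] | None = None,
    rf: RFConfig | None = None,
    max_iter: int = 100,
    alpha: float = 0.01,
    multiple_testing: bool = True,
    seed: int | np.random.Generator = 0,
    keep_history: bool = False,
) -> BorutaResult:
    """Run the shadow-feature all-relevant selection.

    Parameters
    ----------
    X : array-like or DataFrame, shape (n_subjects, n_features)
    y : binary label vector
    rf : forest configuration (trees, mtry, importance measure)
    max_iter : iteration budget; undecided features end tentative
    alpha : two-sided level of the per-feature binomial hit test
    multiple_testing : Bonferroni-adjust alpha by the number of currently
        undecided features (the convention of the reference algorithm)
    """
    rf = rf or RFConfig()
    rng = np.random.default_rng(seed)

    if hasattr(X, "columns"):
        feature_ids = list(X.columns) if feature_ids is None else feature_ids
        X = X.to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
        if feature_ids is None:
            feature_ids = [f"f{j}" for j in range(X.shape[1])]
    y = np.asarray(y)
    n, p = X.shape
    if p < 1:
        raise ValueError("need at least 1 feature")
    if len(np.unique(y)) != 2:
        raise ValueError("labels must contain exactly 2 classes")
    if p < 5:
        warnings.warn(
            "fewer than 5 features: the max-shadow statistic is unstable",
            stacklevel=2,
        )

    undecided = list(range(p))
    decisions = {f: TENTATIVE for f in feature_ids}
    hits = np.zeros(p, dtype=int)
    history: list[dict] = []

    it = 0
    while undecided and it < max_iter:
        it += 1
        idx = np.array(undecided, dtype=int)
        real = X[:, idx]
        # independently shuffled shadow copy of every undecided feature
        shadows = np.empty_like(real)
        for jj in range(real.shape[1]):
            shadows[:, jj] = rng.permutation(real[:, jj])
        ext = np.hstack([real, shadows])

        forest = rf.make_forest(ext.shape[1], rng)
        forest.fit(ext, y)
        imp = _importances(forest, ext, y, rf, rng)
        real_imp, shadow_imp = imp[: len(idx)], imp[len(idx):]
        shadow_max = shadow_imp.max()
        hits[idx] += (real_imp > shadow_max).astype(int)

        if keep_history:
            history.append(
                {
                    "iteration": it,
                    "feature_ids": [feature_ids[j] for j in idx],
                    "importances": real_imp.copy(),
                    "shadow_max": float(shadow_max),
                }
            )

        level = alpha / len(undecided) if multiple_testing else alpha
        # two-sided test split over the tails
        still = []
        for j in idx:
            hi = sps.binom.sf(hits[j] - 1, it, 0.5)   # P(X >= hits)
            lo = sps.binom.cdf(hits[j], it, 0.5)      # P(X <= hits)
            if hi < level / 2:
                decisions[feature_ids[j]] = CONFIRMED
            elif lo < level / 2:
                decisions[feature_ids[j]] = REJECTED
            else:
                still.append(j)
        undecided = still

    return BorutaResult(
        feature_ids=list(feature_ids),
        decisions=decisions,
        hit_counts={f: int(hits[j]) for j, f in enumerate(feature_ids)},
        n_iterations_run=it,
        importance_history=history,
    )
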