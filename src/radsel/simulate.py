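"""Synthetic cohort and feature-table generator.

Emulates the study design this package targets: a two-group cohort
(59 internet-gaming-disorder cases vs 69 healthy controls, with the
published demographic and clinical-scale distributions) and a 2,084-column
radiomic feature table in which a small set of features carries a real
group difference (the eight published discriminative features, planted at
their per-group means and SDs) while every other feature is group-null
noise with block-wise correlation.

All marginals are Gaussian: the source study reports only means and SDs,
so even skewness/kurtosis-type summaries are simulated as Gaussian numbers
whose *names* identify them — the pipeline consumes values, not
distributional pedigree.  Label permutation for null calibration also
lives here.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .schema import FeatureSchema, build_default_schema
from .tables import CASE, CONTROL, GROUP_COLUMN, FeatureTable

__all__ = [
    "CohortConfig",
    "EffectSpec",
    "NoiseConfig",
    "DEFAULT_EFFECTS",
    "generate_cohort",
    "generate_feature_table",
    "permute_labels",
]


@dataclass(frozen=True)
class ScaleParams:
    case_mean: float
    case_sd: float
    control_mean: float
    control_sd: float

    def __post_init__(self) -> None:
        if self.case_sd <= 0 or self.control_sd <= 0:
            raise ValueError("scale SDs must be positive")


def _default_scale_params() -> dict[str, ScaleParams]:
    # Published per-group means +/- SD for age and the four clinical scales.
    return {
        "age": ScaleParams(21.39, 3.06, 20.34, 3.98),
        "cias": ScaleParams(78.27, 10.31, 44.38, 11.34),
        "bis11": ScaleParams(63.02, 7.72, 53.81, 7.42),
        "sas": ScaleParams(50.51, 8.19, 42.65, 6.39),
        "sds": ScaleParams(51.97, 7.09, 45.74, 8.92),
    }


@dataclass(frozen=True)
class CohortConfig:
    """Cohort composition and per-group demographic/scale distributions."""

    n_case: int = 59
    n_control: int = 69
    scale_params: dict[str, ScaleParams] = field(default_factory=_default_scale_params)
    # (male, female) counts per group; defaults are the published sex table.
    case_sex_counts: tuple[int, int] = (47, 12)
    control_sex_counts: tuple[int, int] = (58, 11)
    round_scales: bool = False

    def __post_init__(self) -> None:
        if self.n_case < 2 or self.n_control < 2:
            raise ValueError("each group needs at least 2 subjects")
        if sum(self.case_sex_counts) != self.n_case:
            raise ValueError("case sex counts must sum to n_case")
        if sum(self.control_sex_counts) != self.n_control:
            raise ValueError("control sex counts must sum to n_control")

    def resized(self, n_case: int, n_control: int) -> "CohortConfig":
        """Rescale sex counts proportionally to new group sizes."""
        m = round(n_case * self.case_sex_counts[0] / self.n_case)
        m2 = round(n_control * self.control_sex_counts[0] / self.n_control)
        return replace(
            self,
            n_case=n_case,
            n_control=n_control,
            case_sex_counts=(m, n_case - m),
            control_sex_counts=(m2, n_control - m2),
        )


@dataclass(frozen=True)
class EffectSpec:
    """A planted group difference on one named feature."""

    feature_id: str
    case_mean: float
    case_sd: float
    control_mean: float
    control_sd: float

    def __post_init__(self) -> None:
        if self.case_sd <= 0 or self.control_sd <= 0:
            raise ValueError(f"{self.feature_id}: SDs must be positive")

    @property
    def cohens_d(self) -> float:
        pooled = np.sqrt((self.case_sd**2 + self.control_sd**2) / 2)
        return (self.case_mean - self.control_mean) / pooled


# The eight published discriminative features (per-group mean +/- SD).
# "Internal capsule" is represented by the anterior limb; the pars
# orbitalis row follows the published feature table.
DEFAULT_EFFECTS: tuple[EffectSpec, ...] = (
    EffectSpec("gray.left.rostral_middle_frontal.local_thickness.std", 0.66, 0.05, 0.62, 0.06),
    EffectSpec("white.left.anterior_limb_of_internal_capsule.md.std",
               0.000089, 0.000013, 0.000095, 0.000010),
    EffectSpec("gray.right.fusiform.mean_curvature.mean", -3.83, 0.26, -4.00, 0.23),
    EffectSpec("gray.left.fusiform.local_thickness.skewness", 0.70, 0.22, 0.86, 0.26),
    EffectSpec("gray.left.cuneus.local_thickness.mean", 1.99, 0.17, 1.88, 0.16),
    EffectSpec("white.right.uncinate_fasciculus.md.skewness", 0.25, 0.33, 0.03, 0.32),
    EffectSpec("gray.left.rostral_middle_frontal.travel_depth.skewness", 0.21, 0.02, 0.22, 0.01),
    EffectSpec("gray.left.pars_orbitalis.local_thickness.std", 0.52, 0.05, 0.49, 0.06),
)


@dataclass(frozen=True)
class NoiseConfig:
    """Block-correlated noise for the null features.

    Within blocks of ``block_size`` consecutive null features the pairwise
    correlation is ``within_block_corr`` (equicorrelation via a one-factor
    construction); across blocks features are independent.
    """

    block_size: int = 16
    within_block_corr: float = 0.3

    def __post_init__(self) -> None:
        if self.block_size < 1:
            raise ValueError("block_size must be >= 1")
        if not 0.0 <= self.within_block_corr < 1.0:
            raise ValueError("within_block_corr must lie in [0, 1)")


def compact_schema(include_effects: bool = True) -> FeatureSchema:
    """A reduced feature universe (288 features) for desk-scale runs.

    Contains every default planted-effect feature when ``include_effects``;
    otherwise a smaller universe of labels that carry no default effect.
    Construction mirrors the full schema (regions x measures x statistics),
    just over fewer labels.  Note that all-null *type-I* experiments should
    prefer the full default schema: the screened family's size sets the
    shadow-competition bar, and shrinking the universe changes that regime.
    """
    from .schema import JHU_TRACT_LABELS, SchemaConfig, build_default_schema

    if include_effects:
        regions = ("rostral_middle_frontal", "fusiform", "cuneus", "pars_orbitalis",
                   "caudal_middle_frontal", "lingual", "precuneus", "superior_frontal")
        tracts = tuple(
            (h, t) for h, t in JHU_TRACT_LABELS
            if t in ("anterior_limb_of_internal_capsule", "uncinate_fasciculus",
                     "external_capsule")
        )
    else:
        regions = ("lingual", "precuneus", "postcentral", "supramarginal")
        tracts = tuple(
            (h, t) for h, t in JHU_TRACT_LABELS
            if t in ("external_capsule", "posterior_thalamic_radiation")
        )
    cfg = SchemaConfig(
        cortical_regions=regions,
        tract_labels=tracts,
        subcortical_structures=(),
        gray_measures=("local_thickness", "mean_curvature", "travel_depth"),
        include_volumes=False,
    )
    return build_default_schema(cfg)


def generate_cohort(
    config: CohortConfig | None = None, seed: int | np.random.Generator = 0
) -> pd.DataFrame:
    """Draw a per-subject demographics table.

    Returns a DataFrame indexed by subject id with columns ``group``,
    ``sex`` and one column per configured scale, each drawn from the
    per-group normal distribution.  Sex is assigned to match the configured
    counts exactly.  Deterministic under a fixed seed.
    """
    config = config or CohortConfig()
    rng = np.random.default_rng(seed)

    groups = [CASE] * config.n_case + [CONTROL] * config.n_control
    sexes = (
        ["M"] * config.case_sex_counts[0] + ["F"] * config.case_sex_counts[1]
        + ["M"] * config.control_sex_counts[0] + ["F"] * config.control_sex_counts[1]
    )
    ids = [f"sub-{i + 1:04d}" for i in range(len(groups))]
    out = pd.DataFrame({GROUP_COLUMN: groups, "sex": sexes}, index=pd.Index(ids, name="subject_id"))

    is_case = out[GROUP_COLUMN].to_numpy() == CASE
    for name, p in config.scale_params.items():
        vals = np.where(
            is_case,
            rng.normal(p.case_mean, p.case_sd, len(out)),
            rng.normal(p.control_mean, p.control_sd, len(out)),
        )
        out[name] = np.round(vals) if config.round_scales else vals
    return out


def generate_feature_table(
    schema: FeatureSchema | None = None,
    labels: pd.Series | None = None,
    effects: tuple[EffectSpec, ...] = DEFAULT_EFFECTS,
    noise: NoiseConfig | None = None,
    seed: int | np.random.Generator = 0,
) -> FeatureTable:
    """Generate a feature table over ``schema`` for the given group labels.

    Effect features are drawn N(group mean, group SD) per subject; every
    other feature is N(0, 1) in both groups with block correlation per
    ``noise``.  Column order follows the schema.
    """
    schema = schema or build_default_schema()
    if labels is None:
        labels = generate_cohort(seed=0)[GROUP_COLUMN]
    noise = noise or NoiseConfig()
    rng = np.random.default_rng(seed)

    ids = schema.feature_ids
    id_pos = {fid: j for j, fid in enumerate(ids)}
    for e in effects:
        if e.feature_id not in id_pos:
            raise KeyError(f"effect feature not in schema: {e.feature_id!r}")

    n = len(labels)
    is_case = labels.to_numpy() == CASE
    p = len(ids)
    X = np.empty((n, p))

    effect_cols = {id_pos[e.feature_id] for e in effects}
    null_cols = np.array([j for j in range(p) if j not in effect_cols], dtype=int)

    # Null features: one-factor equicorrelated blocks of consecutive columns.
    rho = noise.within_block_corr
    m = len(null_cols)
    eps = rng.standard_normal((n, m))
    if rho > 0:
        n_blocks = -(-m // noise.block_size)
        factors = rng.standard_normal((n, n_blocks))
        block_of = np.arange(m) // noise.block_size
        Z = np.sqrt(rho) * factors[:, block_of] + np.sqrt(1 - rho) * eps
    else:
        Z = eps
    X[:, null_cols] = Z

    for e in effects:
        j = id_pos[e.feature_id]
        X[:, j] = np.where(
            is_case,
            rng.normal(e.case_mean, e.case_sd, n),
            rng.normal(e.control_mean, e.control_sd, n),
        )

    data = pd.DataFrame(X, index=labels.index, columns=ids)
    return FeatureTable(data, labels.rename(GROUP_COLUMN))


def permute_labels(
    labels: pd.Series | np.ndarray,
    n_perm: int,
    seed: int | np.random.Generator = 0,
) -> list[np.ndarray]:
    """Draw ``n_perm`` independent uniform permutations of the label vector.

    Group sizes are preserved exactly (a permutation rearranges the
    multiset); duplicates across draws are allowed.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    arr = np.asarray(labels)
    return [rng.permutation(arr) for _ in range(n_perm)]
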