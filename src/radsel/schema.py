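"""Radiomic feature schema: the named universe of brain-derived features.

Gray-matter features are vertex-wise cortical shape statistics (local
thickness, geodesic depth, travel depth, mean curvature, convexity)
summarized per DKT cortical region, plus regional volume scalars for the
cortex and subcortical structures.  White-matter features are per-tract
summaries of the four diffusion-tensor scalar maps (FA, MD, RD, AD) over
the 48 JHU-ICBM-81 labels.  The default configuration enumerates 1,316
gray-matter and 768 white-matter descriptors, 2,084 in total.

The schema exists so that the synthetic generator, the screening/selection
stages, and the reports all share one deterministic feature vocabulary;
no image processing happens here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterator, Sequence

__all__ = [
    "FeatureDescriptor",
    "FeatureSchema",
    "SchemaConfig",
    "build_default_schema",
    "DKT_CORTICAL_REGIONS",
    "JHU_TRACT_LABELS",
    "SUBCORTICAL_STRUCTURES",
    "GRAY_SHAPE_MEASURES",
    "DIFFUSION_MEASURES",
    "SUMMARY_STATISTICS",
]

#: 31 DKT cortical parcellation regions (per hemisphere).
DKT_CORTICAL_REGIONS: tuple[str, ...] = (
    "caudal_anterior_cingulate",
    "caudal_middle_frontal",
    "cuneus",
    "entorhinal",
    "fusiform",
    "inferior_parietal",
    "inferior_temporal",
    "isthmus_cingulate",
    "lateral_occipital",
    "lateral_orbitofrontal",
    "lingual",
    "medial_orbitofrontal",
    "middle_temporal",
    "parahippocampal",
    "paracentral",
    "pars_opercularis",
    "pars_orbitalis",
    "pars_triangularis",
    "pericalcarine",
    "postcentral",
    "posterior_cingulate",
    "precentral",
    "precuneus",
    "rostral_anterior_cingulate",
    "rostral_middle_frontal",
    "superior_frontal",
    "superior_parietal",
    "superior_temporal",
    "supramarginal",
    "transverse_temporal",
    "insula",
)

#: JHU-ICBM-DTI-81 white-matter labels: (name, paired) — paired labels exist
#: in both hemispheres, unpaired ones are midline structures.
_JHU_LABELS: tuple[tuple[str, bool], ...] = (
    ("middle_cerebellar_peduncle", False),
    ("pontine_crossing_tract", False),
    ("genu_of_corpus_callosum", False),
    ("body_of_corpus_callosum", False),
    ("splenium_of_corpus_callosum", False),
    ("fornix", False),
    ("corticospinal_tract", True),
    ("medial_lemniscus", True),
    ("inferior_cerebellar_peduncle", True),
    ("superior_cerebellar_peduncle", True),
    ("cerebral_peduncle", True),
    ("anterior_limb_of_internal_capsule", True),
    ("posterior_limb_of_internal_capsule", True),
    ("retrolenticular_part_of_internal_capsule", True),
    ("anterior_corona_radiata", True),
    ("superior_corona_radiata", True),
    ("posterior_corona_radiata", True),
    ("posterior_thalamic_radiation", True),
    ("sagittal_stratum", True),
    ("external_capsule", True),
    ("cingulum_cingulate_gyrus", True),
    ("cingulum_hippocampus", True),
    ("fornix_cres_stria_terminalis", True),
    ("superior_longitudinal_fasciculus", True),
    ("superior_fronto_occipital_fasciculus", True),
    ("uncinate_fasciculus", True),
    ("tapetum", True),
)

#: Flattened (hemisphere, label) pairs: 6 midline + 21 paired x 2 = 48.
JHU_TRACT_LABELS: tuple[tuple[str, str], ...] = tuple(
    (hemi, name)
    for name, paired in _JHU_LABELS
    for hemi in (("left", "right") if paired else ("midline",))
)

#: 7 subcortical structures per hemisphere (14 volume scalars).
SUBCORTICAL_STRUCTURES: tuple[str, ...] = (
    "thalamus",
    "caudate",
    "putamen",
    "pallidum",
    "hippocampus",
    "amygdala",
    "accumbens",
)

GRAY_SHAPE_MEASURES: tuple[str, ...] = (
    "local_thickness",
    "geodesic_depth",
    "travel_depth",
    "mean_curvature",
    "convexity",
)
DIFFUSION_MEASURES: tuple[str, ...] = ("fa", "md", "rd", "ad")
SUMMARY_STATISTICS: tuple[str, ...] = ("mean", "std", "kurtosis", "skewness")

_GRAY_MEASURES = set(GRAY_SHAPE_MEASURES) | {"volume"}
_WHITE_MEASURES = set(DIFFUSION_MEASURES)
_HEMISPHERES = {"left", "right", "midline"}
_STATISTICS = set(SUMMARY_STATISTICS) | {"scalar"}


class SchemaError(ValueError):
    """Raised for invalid schema configurations or unknown feature ids."""


@dataclass(frozen=True)
class FeatureDescriptor:
    """One named radiomic feature: atlas label x measure x summary statistic."""

    tissue: str
    hemisphere: str
    atlas_label: str
    measure: str
    statistic: str

    def __post_init__(self) -> None:
        if self.tissue not in ("gray", "white"):
            raise SchemaError(f"unknown tissue {self.tissue!r}")
        if self.hemisphere not in _HEMISPHERES:
            raise SchemaError(f"unknown hemisphere {self.hemisphere!r}")
        if self.tissue == "white" and self.measure not in _WHITE_MEASURES:
            raise SchemaError(
                f"white-matter feature requires a diffusion measure, got {self.measure!r}"
            )
        if self.tissue == "gray" and self.measure in _WHITE_MEASURES:
            raise SchemaError(
                f"gray-matter feature cannot carry diffusion measure {self.measure!r}"
            )
        if self.measure not in _GRAY_MEASURES | _WHITE_MEASURES:
            raise SchemaError(f"unknown measure {self.measure!r}")
        if self.statistic not in _STATISTICS:
            raise SchemaError(f"unknown statistic {self.statistic!r}")
        if self.measure == "volume" and self.statistic != "scalar":
            raise SchemaError("volume features carry the scalar statistic")

    @property
    def feature_id(self) -> str:
        """Deterministic id: ``tissue.hemisphere.label.measure.statistic``."""
        return ".".join(
            (self.tissue, self.hemisphere, self.atlas_label, self.measure, self.statistic)
        )

    @classmethod
    def from_feature_id(cls, feature_id: str) -> "FeatureDescriptor":
        parts = feature_id.split(".")
        if len(parts) != 5:
            raise SchemaError(f"malformed feature id {feature_id!r}")
        return cls(*parts)


@dataclass(frozen=True)
class SchemaConfig:
    """Factor sets from which the schema is enumerated.

    Defaults reproduce the study's universe: 62 DKT cortical regions,
    48 JHU tract labels, 14 subcortical structures, five vertex-wise shape
    measures and four diffusion measures, each summarized by four
    distribution statistics, plus per-region volume scalars.
    """

    cortical_regions: Sequence[str] = DKT_CORTICAL_REGIONS
    tract_labels: Sequence[tuple[str, str]] = JHU_TRACT_LABELS
    subcortical_structures: Sequence[str] = SUBCORTICAL_STRUCTURES
    gray_measures: Sequence[str] = GRAY_SHAPE_MEASURES
    diffusion_measures: Sequence[str] = DIFFUSION_MEASURES
    statistics: Sequence[str] = SUMMARY_STATISTICS
    include_volumes: bool = True

    def validate(self) -> None:
        for name, labels in (
            ("cortical_regions", tuple(self.cortical_regions)),
            ("tract_labels", tuple(self.tract_labels)),
            ("subcortical_structures", tuple(self.subcortical_structures)),
        ):
            if len(set(labels)) != len(labels):
                raise SchemaError(f"duplicate labels in {name}")


@dataclass
class FeatureSchema:
    """Ordered collection of feature descriptors with a lookup index."""

    descriptors: tuple[FeatureDescriptor, ...]
    _index: dict[str, FeatureDescriptor] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        index: dict[str, FeatureDescriptor] = {}
        for d in self.descriptors:
            if d.feature_id in index:
                raise SchemaError(f"duplicate feature id {d.feature_id!r}")
            index[d.feature_id] = d
        self._index = index

    def __len__(self) -> int:
        return len(self.descriptors)

    def __iter__(self) -> Iterator[FeatureDescriptor]:
        return iter(self.descriptors)

    def __contains__(self, feature_id: str) -> bool:
        return feature_id in self._index

    @property
    def feature_ids(self) -> list[str]:
        return [d.feature_id for d in self.descriptors]

    @property
    def gray_count(self) -> int:
        return sum(1 for d in self.descriptors if d.tissue == "gray")

    @property
    def white_count(self) -> int:
        return sum(1 for d in self.descriptors if d.tissue == "white")

    def lookup(self, feature_id: str) -> FeatureDescriptor:
        """Return the descriptor for ``feature_id`` or raise KeyError naming it."""
        try:
            return self._index[feature_id]
        except KeyError:
            raise KeyError(f"feature id not in schema: {feature_id!r}") from None

    def to_json(self, path) -> None:
        payload = [
            {
                "tissue": d.tissue,
                "hemisphere": d.hemisphere,
                "atlas_label": d.atlas_label,
                "measure": d.measure,
                "statistic": d.statistic,
            }
            for d in self.descriptors
        ]
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "FeatureSchema":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(tuple(FeatureDescriptor(**row) for row in payload))


def build_default_schema(config: SchemaConfig | None = None) -> FeatureSchema:
    """Enumerate the feature universe from a :class:`SchemaConfig`.

    Ordering is deterministic: gray vertex-statistic features (hemisphere,
    region, measure, statistic — in configured order), then cortical volume
    scalars, then subcortical volume scalars, then white-matter tract
    features (tract, measure, statistic).  The default configuration yields
    62*5*4 + 62 + 14 = 1,316 gray and 48*4*4 = 768 white descriptors.
    """
    config = config or SchemaConfig()
    config.validate()

    descriptors: list[FeatureDescriptor] = []
    for hemi in ("left", "right"):
        for region in config.cortical_regions:
            for measure in config.gray_measures:
                for stat in config.statistics:
                    descriptors.append(
                        FeatureDescriptor("gray", hemi, region, measure, stat)
                    )
    if config.include_volumes:
        for hemi in ("left", "right"):
            for region in config.cortical_regions:
                descriptors.append(
                    FeatureDescriptor("gray", hemi, region, "volume", "scalar")
                )
        for hemi in ("left", "right"):
            for structure in config.subcortical_structures:
                descriptors.append(
                    FeatureDescriptor("gray", hemi, structure, "volume", "scalar")
                )
    for hemi, tract in config.tract_labels:
        for measure in config.diffusion_measures:
            for stat in config.statistics:
                descriptors.append(
                    FeatureDescriptor("white", hemi, tract, measure, stat)
                )
    return FeatureSchema(tuple(descriptors))
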