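"""Subjects-by-features table with group labels; CSV/TSV round-tripping.

The on-disk convention is one row per subject, feature ids as column
headers, a ``subject_id`` index column and a single ``group`` column
holding the two class labels (by default ``case``/``control``).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["FeatureTable", "GROUP_COLUMN", "CASE", "CONTROL"]

GROUP_COLUMN = "group"
CASE = "case"
CONTROL = "control"


@dataclass
class FeatureTable:
    """Numeric feature matrix (subjects x features) plus aligned group labels."""

    data: pd.DataFrame          # index: subject ids; columns: feature ids
    labels: pd.Series           # index-aligned group labels

    def __post_init__(self) -> None:
        if not self.data.index.equals(self.labels.index):
            raise ValueError("feature matrix and labels have different subject indexes")
        if GROUP_COLUMN in self.data.columns:
            raise ValueError(f"feature matrix must not contain a {GROUP_COLUMN!r} column")

    @property
    def n_subjects(self) -> int:
        return len(self.data)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def groups(self) -> list:
        return sorted(self.labels.unique())

    def y(self, positive: str = CASE) -> np.ndarray:
        """Binary label vector with 1 for the positive (case) class."""
        return (self.labels.to_numpy() == positive).astype(int)

    def subset_features(self, feature_ids) -> "FeatureTable":
        return FeatureTable(self.data.loc[:, list(feature_ids)], self.labels)

    def subset_subjects(self, idx) -> "FeatureTable":
        return FeatureTable(self.data.iloc[idx], self.labels.iloc[idx])

    def with_labels(self, labels) -> "FeatureTable":
        """Same matrix with a replacement label vector (e.g. a permutation)."""
        new = pd.Series(np.asarray(labels), index=self.data.index, name=GROUP_COLUMN)
        return FeatureTable(self.data, new)

    def to_csv(self, path, sep: str = ",") -> None:
        out = self.data.copy()
        out.insert(0, GROUP_COLUMN, self.labels)
        out.to_csv(path, sep=sep, index_label="subject_id")

    @classmethod
    def from_csv(cls, path, sep: str | None = None) -> "FeatureTable":
        if sep is None:
            sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
        df = pd.read_csv(path, sep=sep, index_col="subject_id")
        if GROUP_COLUMN not in df.columns:
            raise ValueError(
                f"{Path(path).name}: missing required {GROUP_COLUMN!r} column"
            )
        labels = df[GROUP_COLUMN]
        data = df.drop(columns=[GROUP_COLUMN])
        non_numeric = [c for c in data.columns if not np.issubdtype(data[c].dtype, np.number)]
        if non_numeric:
            raise ValueError(f"non-numeric feature columns: {non_numeric[:5]}")
        return cls(data, labels)
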