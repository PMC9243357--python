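"""The patient x feature table with binary response labels.

Labels encode the dichotomized chemotherapy response score: 1 = complete
histopathologic response (CRS3), 0 = non-complete response (CRS1-2).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["FeatureTable"]

LABEL_COLUMN = "label"


@dataclass(frozen=True)
class FeatureTable:
    """Numeric feature matrix (rows: patients) with binary labels."""

    features: pd.DataFrame
    labels: pd.Series

    def __post_init__(self) -> None:
        X = self.features
        y = self.labels
        if len(X) != len(y):
            raise ValueError("features and labels disagree on patient count")
        if X.isna().any().any():
            raise ValueError("feature table contains missing values")
        vals = set(np.unique(y.to_numpy()))
        if not vals <= {0, 1}:
            raise ValueError("labels must be binary 0/1")
        object.__setattr__(self, "labels", y.astype(int))

    @property
    def feature_names(self) -> list[str]:
        return list(self.features.columns)

    @property
    def n_patients(self) -> int:
        return len(self.features)

    @property
    def prevalence(self) -> float:
        return float(self.labels.mean())

    def subset_rows(self, index: np.ndarray) -> "FeatureTable":
        return FeatureTable(self.features.iloc[index], self.labels.iloc[index])

    def subset_features(self, names: list[str]) -> "FeatureTable":
        missing = [n for n in names if n not in self.features.columns]
        if missing:
            raise KeyError(f"features not in table: {missing}")
        return FeatureTable(self.features[list(names)], self.labels)

    def to_csv(self, path: str | Path) -> None:
        df = self.features.copy()
        df[LABEL_COLUMN] = self.labels
        df.to_csv(path, index_label="patient_id")

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureTable":
        df = pd.read_csv(path, index_col="patient_id")
        if LABEL_COLUMN not in df.columns:
            raise ValueError(f"CSV is missing the '{LABEL_COLUMN}' column")
        return cls(df.drop(columns=[LABEL_COLUMN]), df[LABEL_COLUMN])
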