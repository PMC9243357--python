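"""Batch feature extraction: imaging cohort -> patient x feature table."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .features import ExtractionConfig, extract_all, lesion_volume
from .images import CTVolume, load_mask, load_volume
from .tables import FeatureTable

__all__ = ["extract_cohort", "extract_manifest"]


def extract_cohort(
    cohort: list[tuple[CTVolume, np.ndarray, int]],
    config: ExtractionConfig | None = None,
) -> FeatureTable:
    """Extract the 107 radiomic features (plus whole-lesion volume in cm^3)
    for every patient of an in-memory imaging cohort."""
    rows, labels, ids = [], [], []
    for i, (volume, mask, label) in enumerate(cohort):
        feats = extract_all(volume, mask, config)
        feats["volume_cm3"] = lesion_volume(mask, volume.voxel_spacing_mm)
        rows.append(feats)
        labels.append(int(label))
        ids.append(f"P{i:04d}")
    index = pd.Index(ids, name="patient_id")
    return FeatureTable(
        pd.DataFrame(rows, index=index), pd.Series(labels, index=index)
    )


def extract_manifest(
    manifest_csv: str | Path, config: ExtractionConfig | None = None
) -> FeatureTable:
    """Extract features for a cohort described by a NIfTI manifest CSV
    (columns: patient_id, volume, mask, label; paths relative to the CSV)."""
    manifest_path = Path(manifest_csv)
    manifest = pd.read_csv(manifest_path, index_col="patient_id")
    base = manifest_path.parent
    rows, labels = [], []
    for pid, rec in manifest.iterrows():
        volume = load_volume(base / rec["volume"])
        mask = load_mask(base / rec["mask"])
        feats = extract_all(volume, mask, config)
        feats["volume_cm3"] = lesion_volume(mask, volume.voxel_spacing_mm)
        rows.append(feats)
        labels.append(int(rec["label"]))
    index = pd.Index(manifest.index, name="patient_id")
    return FeatureTable(
        pd.DataFrame(rows, index=index), pd.Series(labels, index=index)
    )
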