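"""Gray-Level Run Length Matrix features (runs along 13 directions, averaged)."""

from __future__ import annotations

import numpy as np

from ._grid import DIRECTIONS_13, runs_along_direction
from .firstorder import LOG_EPS

__all__ = ["GLRLM_FEATURE_NAMES", "glrlm_matrix", "compute_glrlm_features"]

GLRLM_FEATURE_NAMES: tuple[str, ...] = (
    "glrlm_GrayLevelNonUniformity",
    "glrlm_GrayLevelNonUniformityNormalized",
    "glrlm_GrayLevelVariance",
    "glrlm_HighGrayLevelRunEmphasis",
    "glrlm_LongRunEmphasis",
    "glrlm_LongRunHighGrayLevelEmphasis",
    "glrlm_LongRunLowGrayLevelEmphasis",
    "glrlm_LowGrayLevelRunEmphasis",
    "glrlm_RunEntropy",
    "glrlm_RunLengthNonUniformity",
    "glrlm_RunLengthNonUniformityNormalized",
    "glrlm_RunPercentage",
    "glrlm_RunVariance",
    "glrlm_ShortRunEmphasis",
    "glrlm_ShortRunHighGrayLevelEmphasis",
    "glrlm_ShortRunLowGrayLevelEmphasis",
)


def glrlm_matrix(
    levels: np.ndarray, mask: np.ndarray, n_levels: int, direction: tuple[int, int, int]
) -> np.ndarray:
    """Run-length matrix P(i, r) for one direction (rows: gray level, cols: length)."""
    gray, lengths = runs_along_direction(levels, mask, direction)
    max_len = int(mask.sum())
    mat = np.zeros((n_levels, max_len), dtype=float)
    np.add.at(mat, (gray - 1, lengths - 1), 1.0)
    return mat


def _features_one(mat: np.ndarray, n_voxels: int) -> dict[str, float]:
    nr = mat.sum()
    i = np.arange(1, mat.shape[0] + 1, dtype=float)
    r = np.arange(1, mat.shape[1] + 1, dtype=float)
    ii, rr = np.meshgrid(i, r, indexing="ij")
    p = mat / nr
    pg = mat.sum(axis=1)  # runs per gray level
    pr = mat.sum(axis=0)  # runs per length
    mu_i = float((p * ii).sum())
    mu_r = float((p * rr).sum())

    f: dict[str, float] = {}
    f["glrlm_GrayLevelNonUniformity"] = float((pg**2).sum() / nr)
    f["glrlm_GrayLevelNonUniformityNormalized"] = float((pg**2).sum() / nr**2)
    f["glrlm_GrayLevelVariance"] = float((p * (ii - mu_i) ** 2).sum())
    f["glrlm_HighGrayLevelRunEmphasis"] = float((mat * ii**2).sum() / nr)
    f["glrlm_LongRunEmphasis"] = float((mat * rr**2).sum() / nr)
    f["glrlm_LongRunHighGrayLevelEmphasis"] = float((mat * ii**2 * rr**2).sum() / nr)
    f["glrlm_LongRunLowGrayLevelEmphasis"] = float((mat * rr**2 / ii**2).sum() / nr)
    f["glrlm_LowGrayLevelRunEmphasis"] = float((mat / ii**2).sum() / nr)
    f["glrlm_RunEntropy"] = float(-(p * np.log2(p + LOG_EPS)).sum())
    f["glrlm_RunLengthNonUniformity"] = float((pr**2).sum() / nr)
    f["glrlm_RunLengthNonUniformityNormalized"] = float((pr**2).sum() / nr**2)
    f["glrlm_RunPercentage"] = float(nr / n_voxels)
    f["glrlm_RunVariance"] = float((p * (rr - mu_r) ** 2).sum())
    f["glrlm_ShortRunEmphasis"] = float((mat / rr**2).sum() / nr)
    f["glrlm_ShortRunHighGrayLevelEmphasis"] = float((mat * ii**2 / rr**2).sum() / nr)
    f["glrlm_ShortRunLowGrayLevelEmphasis"] = float((mat / (ii**2 * rr**2)).sum() / nr)
    return f


def compute_glrlm_features(
    levels: np.ndarray, mask: np.ndarray, n_levels: int
) -> dict[str, float]:
    """Compute the 16 GLRLM features averaged over the 13 directions."""
    n_voxels = int(mask.sum())
    if n_voxels == 0:
        raise ValueError("empty mask")
    per_dir = []
    for direction in DIRECTIONS_13:
        mat = glrlm_matrix(levels, mask, n_levels, direction)
        per_dir.append(_features_one(mat, n_voxels))
    return {
        name: float(np.mean([f[name] for f in per_dir])) for name in GLRLM_FEATURE_NAMES
    }
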