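"""Gray-Level Size Zone Matrix features (26-connected zones, single matrix)."""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .firstorder import LOG_EPS

__all__ = ["GLSZM_FEATURE_NAMES", "glszm_matrix", "compute_glszm_features"]

GLSZM_FEATURE_NAMES: tuple[str, ...] = (
    "glszm_GrayLevelNonUniformity",
    "glszm_GrayLevelNonUniformityNormalized",
    "glszm_GrayLevelVariance",
    "glszm_HighGrayLevelZoneEmphasis",
    "glszm_LargeAreaEmphasis",
    "glszm_LargeAreaHighGrayLevelEmphasis",
    "glszm_LargeAreaLowGrayLevelEmphasis",
    "glszm_LowGrayLevelZoneEmphasis",
    "glszm_SizeZoneNonUniformity",
    "glszm_SizeZoneNonUniformityNormalized",
    "glszm_SmallAreaEmphasis",
    "glszm_SmallAreaHighGrayLevelEmphasis",
    "glszm_SmallAreaLowGrayLevelEmphasis",
    "glszm_ZoneEntropy",
    "glszm_ZonePercentage",
    "glszm_ZoneVariance",
)

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


def glszm_matrix(levels: np.ndarray, mask: np.ndarray, n_levels: int) -> np.ndarray:
    """Size-zone matrix P(i, s): zones of 26-connected equal-level voxels."""
    max_size = int(mask.sum())
    mat = np.zeros((n_levels, max_size), dtype=float)
    for g in np.unique(levels[mask]):
        lab, n_zones = ndimage.label((levels == g) & mask, structure=_STRUCT_26)
        if n_zones == 0:
            continue
        sizes = np.bincount(lab.ravel())[1:]
        np.add.at(mat, (g - 1, sizes - 1), 1.0)
    return mat


def compute_glszm_features(
    levels: np.ndarray, mask: np.ndarray, n_levels: int
) -> dict[str, float]:
    """Compute the 16 GLSZM features."""
    n_voxels = int(mask.sum())
    if n_voxels == 0:
        raise ValueError("empty mask")
    mat = glszm_matrix(levels, mask, n_levels)
    nz = mat.sum()
    i = np.arange(1, mat.shape[0] + 1, dtype=float)
    s = np.arange(1, mat.shape[1] + 1, dtype=float)
    ii, ss = np.meshgrid(i, s, indexing="ij")
    p = mat / nz
    pg = mat.sum(axis=1)
    ps = mat.sum(axis=0)
    mu_i = float((p * ii).sum())
    mu_s = float((p * ss).sum())

    f: dict[str, float] = {}
    f["glszm_GrayLevelNonUniformity"] = float((pg**2).sum() / nz)
    f["glszm_GrayLevelNonUniformityNormalized"] = float((pg**2).sum() / nz**2)
    f["glszm_GrayLevelVariance"] = float((p * (ii - mu_i) ** 2).sum())
    f["glszm_HighGrayLevelZoneEmphasis"] = float((mat * ii**2).sum() / nz)
    f["glszm_LargeAreaEmphasis"] = float((mat * ss**2).sum() / nz)
    f["glszm_LargeAreaHighGrayLevelEmphasis"] = float((mat * ii**2 * ss**2).sum() / nz)
    f["glszm_LargeAreaLowGrayLevelEmphasis"] = float((mat * ss**2 / ii**2).sum() / nz)
    f["glszm_LowGrayLevelZoneEmphasis"] = float((mat / ii**2).sum() / nz)
    f["glszm_SizeZoneNonUniformity"] = float((ps**2).sum() / nz)
    f["glszm_SizeZoneNonUniformityNormalized"] = float((ps**2).sum() / nz**2)
    f["glszm_SmallAreaEmphasis"] = float((mat / ss**2).sum() / nz)
    f["glszm_SmallAreaHighGrayLevelEmphasis"] = float((mat * ii**2 / ss**2).sum() / nz)
    f["glszm_SmallAreaLowGrayLevelEmphasis"] = float((mat / (ii**2 * ss**2)).sum() / nz)
    f["glszm_ZoneEntropy"] = float(-(p * np.log2(p + LOG_EPS)).sum())
    f["glszm_ZonePercentage"] = float(nz / n_voxels)
    f["glszm_ZoneVariance"] = float((p * (ss - mu_s) ** 2).sum())
    return f
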