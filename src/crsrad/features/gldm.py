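"""Gray-Level Dependence Matrix features (26-neighborhood, tolerance alpha = 0)."""

from __future__ import annotations

import numpy as np

from ._grid import OFFSETS_26
from .firstorder import LOG_EPS

__all__ = ["GLDM_FEATURE_NAMES", "gldm_matrix", "compute_gldm_features"]

GLDM_FEATURE_NAMES: tuple[str, ...] = (
    "gldm_DependenceEntropy",
    "gldm_DependenceNonUniformity",
    "gldm_DependenceNonUniformityNormalized",
    "gldm_DependenceVariance",
    "gldm_GrayLevelNonUniformity",
    "gldm_GrayLevelVariance",
    "gldm_HighGrayLevelEmphasis",
    "gldm_LargeDependenceEmphasis",
    "gldm_LargeDependenceHighGrayLevelEmphasis",
    "gldm_LargeDependenceLowGrayLevelEmphasis",
    "gldm_LowGrayLevelEmphasis",
    "gldm_SmallDependenceEmphasis",
    "gldm_SmallDependenceHighGrayLevelEmphasis",
    "gldm_SmallDependenceLowGrayLevelEmphasis",
)


def _shift(arr: np.ndarray, offset: tuple[int, int, int], fill) -> np.ndarray:
    out = np.full_like(arr, fill)
    src, dst = [], []
    for d in offset:
        if d == 0:
            src.append(slice(None))
            dst.append(slice(None))
        elif d > 0:
            src.append(slice(d, None))
            dst.append(slice(None, -d))
        else:
            src.append(slice(None, d))
            dst.append(slice(-d, None))
    out[tuple(dst)] = arr[tuple(src)]
    return out


def gldm_matrix(
    levels: np.ndarray, mask: np.ndarray, n_levels: int, alpha: int = 0
) -> np.ndarray:
    """Dependence matrix P(i, j): voxels of level i with dependence size j.

    The dependence size of a voxel counts itself plus its in-mask
    26-neighbors whose gray level differs by at most ``alpha``, so sizes run
    from 1 to 27.
    """
    dep = np.ones(mask.shape, dtype=np.int32)  # the center voxel itself
    for off in OFFSETS_26:
        nb_lv = _shift(levels, off, 0)
        nb_in = _shift(mask, off, False)
        dep += (mask & nb_in & (np.abs(levels - nb_lv) <= alpha)).astype(np.int32)
    mat = np.zeros((n_levels, 27), dtype=float)
    np.add.at(mat, (levels[mask] - 1, dep[mask] - 1), 1.0)
    return mat


def compute_gldm_features(
    levels: np.ndarray, mask: np.ndarray, n_levels: int, alpha: int = 0
) -> dict[str, float]:
    """Compute the 14 GLDM features."""
    if not mask.any():
        raise ValueError("empty mask")
    mat = gldm_matrix(levels, mask, n_levels, alpha=alpha)
    nz = mat.sum()
    i = np.arange(1, mat.shape[0] + 1, dtype=float)
    j = np.arange(1, mat.shape[1] + 1, dtype=float)
    ii, jj = np.meshgrid(i, j, indexing="ij")
    p = mat / nz
    pg = mat.sum(axis=1)
    pd = mat.sum(axis=0)
    mu_i = float((p * ii).sum())
    mu_j = float((p * jj).sum())

    f: dict[str, float] = {}
    f["gldm_DependenceEntropy"] = float(-(p * np.log2(p + LOG_EPS)).sum())
    f["gldm_DependenceNonUniformity"] = float((pd**2).sum() / nz)
    f["gldm_DependenceNonUniformityNormalized"] = float((pd**2).sum() / nz**2)
    f["gldm_DependenceVariance"] = float((p * (jj - mu_j) ** 2).sum())
    f["gldm_GrayLevelNonUniformity"] = float((pg**2).sum() / nz)
    f["gldm_GrayLevelVariance"] = float((p * (ii - mu_i) ** 2).sum())
    f["gldm_HighGrayLevelEmphasis"] = float((mat * ii**2).sum() / nz)
    f["gldm_LargeDependenceEmphasis"] = float((mat * jj**2).sum() / nz)
    f["gldm_LargeDependenceHighGrayLevelEmphasis"] = float(
        (mat * ii**2 * jj**2).sum() / nz
    )
    f["gldm_LargeDependenceLowGrayLevelEmphasis"] = float(
        (mat * jj**2 / ii**2).sum() / nz
    )
    f["gldm_LowGrayLevelEmphasis"] = float((mat / ii**2).sum() / nz)
    f["gldm_SmallDependenceEmphasis"] = float((mat / jj**2).sum() / nz)
    f["gldm_SmallDependenceHighGrayLevelEmphasis"] = float(
        (mat * ii**2 / jj**2).sum() / nz
    )
    f["gldm_SmallDependenceLowGrayLevelEmphasis"] = float(
        (mat / (ii**2 * jj**2)).sum() / nz
    )
    return f
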