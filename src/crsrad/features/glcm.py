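"""Gray-Level Co-occurrence Matrix features.

Symmetric co-occurrence matrices are built at distance 1 for the 13 unique
3D directions; each feature is evaluated per directional matrix and the
unweighted mean over directions is reported.
"""

from __future__ import annotations

import numpy as np

from ._grid import DIRECTIONS_13, shifted_pairs
from .firstorder import LOG_EPS

__all__ = ["GLCM_FEATURE_NAMES", "glcm_matrices", "compute_glcm_features"]

GLCM_FEATURE_NAMES: tuple[str, ...] = (
    "glcm_Autocorrelation",
    "glcm_ClusterProminence",
    "glcm_ClusterShade",
    "glcm_ClusterTendency",
    "glcm_Contrast",
    "glcm_Correlation",
    "glcm_DifferenceAverage",
    "glcm_DifferenceEntropy",
    "glcm_DifferenceVariance",
    "glcm_Id",
    "glcm_Idm",
    "glcm_Idmn",
    "glcm_Idn",
    "glcm_Imc1",
    "glcm_Imc2",
    "glcm_InverseVariance",
    "glcm_JointAverage",
    "glcm_JointEnergy",
    "glcm_JointEntropy",
    "glcm_MCC",
    "glcm_MaximumProbability",
    "glcm_SumAverage",
    "glcm_SumEntropy",
    "glcm_SumSquares",
)


def glcm_matrices(levels: np.ndarray, mask: np.ndarray, n_levels: int) -> list[np.ndarray]:
    """Normalized symmetric co-occurrence matrices, one per direction.

    Directions with no valid voxel pair (possible for very small masks) are
    skipped.
    """
    mats = []
    for direction in DIRECTIONS_13:
        a, b = shifted_pairs(levels, mask, direction)
        if a.size == 0:
            continue
        counts = np.zeros((n_levels, n_levels), dtype=float)
        np.add.at(counts, (a - 1, b - 1), 1.0)
        counts += counts.T  # symmetric: count each pair in both orders
        mats.append(counts / counts.sum())
    return mats


def _mcc(p: np.ndarray, px: np.ndarray) -> float:
    """Maximal correlation coefficient: sqrt of the 2nd-largest eigenvalue of Q."""
    keep = px > 0
    if keep.sum() < 2:
        return 1.0
    pk = p[np.ix_(keep, keep)]
    pxk = px[keep]
    # Q(i,j) = sum_k p(i,k) p(j,k) / (px(i) py(k)); symmetric GLCM => py = px
    q = (pk / pxk[:, None]) @ (pk / pxk[None, :]).T
    eig = np.sort(np.abs(np.linalg.eigvals(q)))
    return float(np.sqrt(np.clip(eig[-2], 0.0, 1.0)))


def _features_one(p: np.ndarray, n_levels: int) -> dict[str, float]:
    ng = n_levels
    i = np.arange(1, ng + 1, dtype=float)
    ii, jj = np.meshgrid(i, i, indexing="ij")

    px = p.sum(axis=1)
    mu_x = float((px * i).sum())
    sig_x = float(np.sqrt((px * (i - mu_x) ** 2).sum()))

    diff = np.abs(ii - jj).astype(int)
    p_diff = np.bincount(diff.ravel(), weights=p.ravel(), minlength=ng)
    k_diff = np.arange(ng, dtype=float)
    summ = (ii + jj).astype(int)
    p_sum = np.bincount(summ.ravel(), weights=p.ravel(), minlength=2 * ng + 1)[2:]
    k_sum = np.arange(2, 2 * ng + 1, dtype=float)

    da = float((k_diff * p_diff).sum())
    hx = float(-(px * np.log2(px + LOG_EPS)).sum())
    hxy = float(-(p * np.log2(p + LOG_EPS)).sum())
    pxpy = np.outer(px, px)
    hxy1 = float(-(p * np.log2(pxpy + LOG_EPS)).sum())
    hxy2 = float(-(pxpy * np.log2(pxpy + LOG_EPS)).sum())

    f: dict[str, float] = {}
    f["glcm_Autocorrelation"] = float((p * ii * jj).sum())
    f["glcm_ClusterProminence"] = float((p * (ii + jj - 2 * mu_x) ** 4).sum())
    f["glcm_ClusterShade"] = float((p * (ii + jj - 2 * mu_x) ** 3).sum())
    f["glcm_ClusterTendency"] = float((p * (ii + jj - 2 * mu_x) ** 2).sum())
    f["glcm_Contrast"] = float((p * (ii - jj) ** 2).sum())
    f["glcm_Correlation"] = (
        float(((p * ii * jj).sum() - mu_x**2) / sig_x**2) if sig_x > 0 else 1.0
    )
    f["glcm_DifferenceAverage"] = da
    f["glcm_DifferenceEntropy"] = float(-(p_diff * np.log2(p_diff + LOG_EPS)).sum())
    f["glcm_DifferenceVariance"] = float((p_diff * (k_diff - da) ** 2).sum())
    f["glcm_Id"] = float((p / (1.0 + np.abs(ii - jj))).sum())
    f["glcm_Idm"] = float((p / (1.0 + (ii - jj) ** 2)).sum())
    f["glcm_Idmn"] = float((p / (1.0 + (ii - jj) ** 2 / ng**2)).sum())
    f["glcm_Idn"] = float((p / (1.0 + np.abs(ii - jj) / ng)).sum())
    f["glcm_Imc1"] = (hxy - hxy1) / max(hx, LOG_EPS) if hx > 0 else 0.0
    f["glcm_Imc2"] = float(np.sqrt(np.clip(1.0 - np.exp(-2.0 * (hxy2 - hxy)), 0.0, 1.0)))
    off = diff > 0
    f["glcm_InverseVariance"] = float((p[off] / (ii - jj)[off] ** 2).sum())
    f["glcm_JointAverage"] = float((p * ii).sum())
    f["glcm_JointEnergy"] = float((p**2).sum())
    f["glcm_JointEntropy"] = hxy
    f["glcm_MCC"] = _mcc(p, px)
    f["glcm_MaximumProbability"] = float(p.max())
    f["glcm_SumAverage"] = float((k_sum * p_sum).sum())
    f["glcm_SumEntropy"] = float(-(p_sum * np.log2(p_sum + LOG_EPS)).sum())
    f["glcm_SumSquares"] = float((p * (ii - mu_x) ** 2).sum())
    return f


def compute_glcm_features(
    levels: np.ndarray, mask: np.ndarray, n_levels: int
) -> dict[str, float]:
    """Compute the 24 GLCM features averaged over the 13 directions."""
    mats = glcm_matrices(levels, mask, n_levels)
    if not mats:
        # single voxel: no co-occurring pairs in any direction
        base = {name: 0.0 for name in GLCM_FEATURE_NAMES}
        base["glcm_Idmn"] = 1.0
        base["glcm_Id"] = base["glcm_Idm"] = base["glcm_Idn"] = 1.0
        base["glcm_MaximumProbability"] = 1.0
        base["glcm_JointEnergy"] = 1.0
        base["glcm_MCC"] = 1.0
        base["glcm_Correlation"] = 1.0
        return base
    per_dir = [_features_one(p, n_levels) for p in mats]
    return {
        name: float(np.mean([f[name] for f in per_dir])) for name in GLCM_FEATURE_NAMES
    }
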