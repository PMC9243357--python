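"""First-order intensity-histogram statistics on resegmented lesion voxels."""

from __future__ import annotations

import numpy as np
from scipy import stats

__all__ = ["FIRSTORDER_FEATURE_NAMES", "compute_first_order"]

LOG_EPS = 1e-16

FIRSTORDER_FEATURE_NAMES: tuple[str, ...] = (
    "firstorder_Energy",
    "firstorder_TotalEnergy",
    "firstorder_Entropy",
    "firstorder_Minimum",
    "firstorder_10Percentile",
    "firstorder_90Percentile",
    "firstorder_Maximum",
    "firstorder_Mean",
    "firstorder_Median",
    "firstorder_InterquartileRange",
    "firstorder_Range",
    "firstorder_MeanAbsoluteDeviation",
    "firstorder_RobustMeanAbsoluteDeviation",
    "firstorder_RootMeanSquared",
    "firstorder_Skewness",
    "firstorder_Kurtosis",
    "firstorder_Variance",
    "firstorder_Uniformity",
)


def compute_first_order(
    values: np.ndarray, levels: np.ndarray, voxel_volume_mm3: float
) -> dict[str, float]:
    """Compute the 18 first-order features.

    Parameters
    ----------
    values:
        Resegmented voxel intensities in HU (1D).
    levels:
        Gray level of each voxel (1D, aligned with ``values``); entropy and
        uniformity are computed on this discretized histogram.
    voxel_volume_mm3:
        Physical volume of one voxel, used for total energy.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("no voxels")
    lv = np.asarray(levels).ravel()
    if lv.size != v.size:
        raise ValueError("levels must align with values")

    p = np.bincount(lv)[1:].astype(float)
    p = p[p > 0] / v.size

    p10, p25, p50, p75, p90 = np.percentile(v, [10, 25, 50, 75, 90])
    mean = float(v.mean())
    robust = v[(v >= p10) & (v <= p90)]

    f: dict[str, float] = {}
    f["firstorder_Energy"] = float(np.sum(v**2))
    f["firstorder_TotalEnergy"] = float(voxel_volume_mm3 * np.sum(v**2))
    f["firstorder_Entropy"] = float(-np.sum(p * np.log2(p + LOG_EPS)))
    f["firstorder_Minimum"] = float(v.min())
    f["firstorder_10Percentile"] = float(p10)
    f["firstorder_90Percentile"] = float(p90)
    f["firstorder_Maximum"] = float(v.max())
    f["firstorder_Mean"] = mean
    f["firstorder_Median"] = float(p50)
    f["firstorder_InterquartileRange"] = float(p75 - p25)
    f["firstorder_Range"] = float(v.max() - v.min())
    f["firstorder_MeanAbsoluteDeviation"] = float(np.abs(v - mean).mean())
    f["firstorder_RobustMeanAbsoluteDeviation"] = (
        float(np.abs(robust - robust.mean()).mean()) if robust.size else 0.0
    )
    f["firstorder_RootMeanSquared"] = float(np.sqrt(np.mean(v**2)))
    # population (biased) moments; kurtosis is reported non-excess.
    # Both are defined as 0 for (near-)constant samples.
    if v.size > 1 and v.var() > 0:
        f["firstorder_Skewness"] = float(stats.skew(v, bias=True))
        f["firstorder_Kurtosis"] = float(stats.kurtosis(v, fisher=False, bias=True))
    else:
        f["firstorder_Skewness"] = 0.0
        f["firstorder_Kurtosis"] = 0.0
    f["firstorder_Variance"] = float(v.var())
    f["firstorder_Uniformity"] = float(np.sum(p**2))
    return f
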