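"""Neighboring Gray Tone Difference Matrix features (26-neighborhood)."""

from __future__ import annotations

import numpy as np

from ._grid import OFFSETS_26
from .gldm import _shift

__all__ = ["NGTDM_FEATURE_NAMES", "ngtdm_table", "compute_ngtdm_features"]

NGTDM_FEATURE_NAMES: tuple[str, ...] = (
    "ngtdm_Busyness",
    "ngtdm_Coarseness",
    "ngtdm_Complexity",
    "ngtdm_Contrast",
    "ngtdm_Strength",
)


def ngtdm_table(levels: np.ndarray, mask: np.ndarray, n_levels: int):
    """Per-gray-level voxel counts n_i and summed absolute differences s_i.

    s_i sums |i - A| over voxels of level i, where A is the mean level of the
    voxel's in-mask 26-neighbors; voxels without any in-mask neighbor
    contribute zero difference.
    """
    nb_sum = np.zeros(mask.shape, dtype=float)
    nb_cnt = np.zeros(mask.shape, dtype=float)
    for off in OFFSETS_26:
        nb_in = _shift(mask, off, False)
        nb_lv = _shift(levels, off, 0)
        nb_sum += np.where(nb_in, nb_lv, 0.0)
        nb_cnt += nb_in.astype(float)
    diff = np.zeros(mask.shape, dtype=float)
    has_nb = mask & (nb_cnt > 0)
    diff[has_nb] = np.abs(levels[has_nb] - nb_sum[has_nb] / nb_cnt[has_nb])
    n_i = np.bincount(levels[mask] - 1, minlength=n_levels).astype(float)
    s_i = np.bincount(levels[mask] - 1, weights=diff[mask], minlength=n_levels)
    return n_i, s_i


def compute_ngtdm_features(
    levels: np.ndarray, mask: np.ndarray, n_levels: int
) -> dict[str, float]:
    """Compute the 5 NGTDM features."""
    nvp = int(mask.sum())
    if nvp == 0:
        raise ValueError("empty mask")
    n_i, s_i = ngtdm_table(levels, mask, n_levels)
    p_i = n_i / nvp
    present = p_i > 0
    ngp = int(present.sum())
    i = np.arange(1, n_levels + 1, dtype=float)

    f: dict[str, float] = {}
    denom_coarse = float((p_i * s_i).sum())
    f["ngtdm_Coarseness"] = 1.0 / denom_coarse if denom_coarse > 0 else 1e6

    if ngp > 1:
        ip, pp, sp = i[present], p_i[present], s_i[present]
        d2 = (ip[:, None] - ip[None, :]) ** 2
        pij = pp[:, None] * pp[None, :]
        f["ngtdm_Contrast"] = float(
            (pij * d2).sum() / (ngp * (ngp - 1)) * s_i.sum() / nvp
        )
        busy_den = float(np.abs(ip[:, None] * pp[:, None] - ip[None, :] * pp[None, :]).sum())
        f["ngtdm_Busyness"] = denom_coarse / busy_den if busy_den > 0 else 0.0
        psum = pp[:, None] + pp[None, :]
        num = np.abs(ip[:, None] - ip[None, :]) * (
            pp[:, None] * sp[:, None] + pp[None, :] * sp[None, :]
        )
        f["ngtdm_Complexity"] = float((num / psum).sum() / nvp)
        s_total = float(s_i.sum())
        f["ngtdm_Strength"] = float((psum * d2).sum() / s_total) if s_total > 0 else 0.0
    else:
        f["ngtdm_Contrast"] = 0.0
        f["ngtdm_Busyness"] = 0.0
        f["ngtdm_Complexity"] = 0.0
        f["ngtdm_Strength"] = 0.0
    return f
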