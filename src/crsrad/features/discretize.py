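"""HU resegmentation, tissue sub-segmentation and gray-level discretization.

Texture features are computed on lesion voxels restricted to a Hounsfield
range (default [-100, 400] HU, the soft-tissue window) and then quantized
into gray levels whose bin width follows the Freedman-Diaconis rule on the
resegmented intensity sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..images import CTVolume, check_mask

__all__ = [
    "DEFAULT_RESEGMENTATION_RANGE_HU",
    "FD_FALLBACK_BIN_WIDTH_HU",
    "DiscretizationSpec",
    "TISSUE_LABELS",
    "subsegment_tissue",
    "resegment",
    "fd_bin_width",
    "build_discretization",
    "discretize",
]

DEFAULT_RESEGMENTATION_RANGE_HU: tuple[float, float] = (-100.0, 400.0)
#: Bin width used when the Freedman-Diaconis rule degenerates (IQR = 0).
FD_FALLBACK_BIN_WIDTH_HU: float = 25.0

#: Integer codes of the tissue label map.
TISSUE_LABELS = {"background": 0, "hypodense": 1, "soft_tissue": 2, "hyperdense": 3}


@dataclass(frozen=True)
class DiscretizationSpec:
    """Gray-level quantization derived from a voxel sample.

    Attributes
    ----------
    resegmentation_range_hu:
        Closed HU interval; voxels outside it are dropped before texture
        computation.
    bin_width:
        Width of one gray-level bin in HU.
    n_levels:
        Number of gray levels; at least 1.
    minimum:
        Intensity anchored to the lower edge of level 1 (the resegmented
        lesion minimum).
    """

    resegmentation_range_hu: tuple[float, float] = DEFAULT_RESEGMENTATION_RANGE_HU
    bin_width: float = FD_FALLBACK_BIN_WIDTH_HU
    n_levels: int = 1
    minimum: float = 0.0

    def __post_init__(self) -> None:
        lo, hi = self.resegmentation_range_hu
        if not lo < hi:
            raise ValueError("resegmentation range must satisfy lower < upper")
        if self.bin_width <= 0:
            raise ValueError("bin width must be positive")
        if self.n_levels < 1:
            raise ValueError("need at least one gray level")


def subsegment_tissue(
    volume: CTVolume,
    mask: np.ndarray,
    lower_hu: float = DEFAULT_RESEGMENTATION_RANGE_HU[0],
    upper_hu: float = DEFAULT_RESEGMENTATION_RANGE_HU[1],
) -> np.ndarray:
    """Partition lesion voxels into hypodense / soft-tissue / hyperdense classes.

    Voxels below ``lower_hu`` are labelled hypodense (fat, cystic or necrotic
    material), voxels above ``upper_hu`` hyperdense (calcification), and the
    rest soft tissue. Voxels outside the mask keep the background label 0.
    """
    if not lower_hu < upper_hu:
        raise ValueError("lower_hu must be below upper_hu")
    m = check_mask(mask, volume)
    if not m.any():
        raise ValueError("empty lesion mask")
    hu = volume.intensities
    labels = np.zeros(m.shape, dtype=np.uint8)
    labels[m] = TISSUE_LABELS["soft_tissue"]
    labels[m & (hu < lower_hu)] = TISSUE_LABELS["hypodense"]
    labels[m & (hu > upper_hu)] = TISSUE_LABELS["hyperdense"]
    return labels


def resegment(
    volume: CTVolume,
    mask: np.ndarray,
    range_hu: tuple[float, float] = DEFAULT_RESEGMENTATION_RANGE_HU,
) -> np.ndarray:
    """Drop mask voxels whose intensity lies outside the closed HU range.

    Shape features are computed on the original mask; first-order and texture
    features use the mask returned here.
    """
    lo, hi = range_hu
    if not lo < hi:
        raise ValueError("resegmentation range must satisfy lower < upper")
    m = check_mask(mask, volume)
    hu = volume.intensities
    out = m & (hu >= lo) & (hu <= hi)
    if not out.any():
        raise ValueError(
            "resegmentation removed every lesion voxel; widen the HU range"
        )
    return out


def fd_bin_width(values: np.ndarray, fallback: float = FD_FALLBACK_BIN_WIDTH_HU) -> float:
    """Freedman-Diaconis bin width ``2 * IQR * n**(-1/3)``.

    Falls back to a fixed width when the interquartile range is zero
    (constant or near-constant samples), for which the rule is undefined.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size < 2:
        raise ValueError("need at least two values for the Freedman-Diaconis rule")
    q25, q75 = np.percentile(v, [25.0, 75.0])
    iqr = q75 - q25
    if iqr <= 0:
        return float(fallback)
    return float(2.0 * iqr * v.size ** (-1.0 / 3.0))


def build_discretization(
    values: np.ndarray,
    range_hu: tuple[float, float] = DEFAULT_RESEGMENTATION_RANGE_HU,
    fallback: float = FD_FALLBACK_BIN_WIDTH_HU,
) -> DiscretizationSpec:
    """Derive the gray-level quantization for a resegmented voxel sample."""
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("no voxels to discretize")
    width = fd_bin_width(v, fallback=fallback) if v.size >= 2 else float(fallback)
    vmin, vmax = float(v.min()), float(v.max())
    # fixed-bin-size convention: the maximum opens a final bin of its own,
    # so a two-valued sample separated by exactly one width gets two levels
    n_levels = int(np.floor((vmax - vmin) / width)) + 1 if vmax > vmin else 1
    return DiscretizationSpec(
        resegmentation_range_hu=range_hu,
        bin_width=width,
        n_levels=n_levels,
        minimum=vmin,
    )


def discretize(volume: CTVolume, mask: np.ndarray, spec: DiscretizationSpec) -> np.ndarray:
    """Map intensities to gray levels ``1..n_levels``; 0 outside the mask.

    Level of a voxel with value v is ``floor((v - minimum)/bin_width) + 1``,
    capped at ``n_levels`` so the maximum falls in the top bin.
    """
    m = check_mask(mask, volume)
    if not m.any():
        raise ValueError("empty mask")
    levels = np.zeros(m.shape, dtype=np.int32)
    v = volume.intensities[m]
    lv = np.floor((v - spec.minimum) / spec.bin_width).astype(np.int32) + 1
    np.clip(lv, 1, spec.n_levels, out=lv)
    levels[m] = lv
    return levels
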