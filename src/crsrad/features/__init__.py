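"""Radiomic feature extraction for omental lesions on CT.

The full original-image feature set comprises 107 features in seven classes
(shape 14, first-order 18, GLCM 24, GLRLM 16, GLSZM 16, GLDM 14, NGTDM 5).
Shape features are computed on the original mask; first-order and texture
features on the mask resegmented to the soft-tissue HU window and quantized
with a Freedman-Diaconis bin width, at the original voxel sizes (no
resampling).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..images import CTVolume, check_mask
from .discretize import (
    DEFAULT_RESEGMENTATION_RANGE_HU,
    FD_FALLBACK_BIN_WIDTH_HU,
    DiscretizationSpec,
    build_discretization,
    discretize,
    fd_bin_width,
    resegment,
    subsegment_tissue,
)
from .firstorder import FIRSTORDER_FEATURE_NAMES, compute_first_order
from .glcm import GLCM_FEATURE_NAMES, compute_glcm_features
from .gldm import GLDM_FEATURE_NAMES, compute_gldm_features
from .glrlm import GLRLM_FEATURE_NAMES, compute_glrlm_features
from .glszm import GLSZM_FEATURE_NAMES, compute_glszm_features
from .ngtdm import NGTDM_FEATURE_NAMES, compute_ngtdm_features
from .shape import (
    SHAPE_FEATURE_NAMES,
    compute_shape_features,
    lesion_volume,
    percentage_change,
)

__all__ = [
    "FEATURE_CLASSES",
    "ALL_FEATURE_NAMES",
    "SIGNATURE_FEATURE_NAMES",
    "ExtractionConfig",
    "extract_all",
    "compute_signature",
    "subsegment_tissue",
    "resegment",
    "fd_bin_width",
    "build_discretization",
    "discretize",
    "DiscretizationSpec",
    "compute_shape_features",
    "compute_first_order",
    "compute_glcm_features",
    "compute_glrlm_features",
    "compute_glszm_features",
    "compute_gldm_features",
    "compute_ngtdm_features",
    "lesion_volume",
    "percentage_change",
]

#: Feature names by class, in reporting order.
FEATURE_CLASSES: dict[str, tuple[str, ...]] = {
    "shape": SHAPE_FEATURE_NAMES,
    "firstorder": FIRSTORDER_FEATURE_NAMES,
    "glcm": GLCM_FEATURE_NAMES,
    "glrlm": GLRLM_FEATURE_NAMES,
    "glszm": GLSZM_FEATURE_NAMES,
    "gldm": GLDM_FEATURE_NAMES,
    "ngtdm": NGTDM_FEATURE_NAMES,
}

#: The 107 feature names in canonical order.
ALL_FEATURE_NAMES: tuple[str, ...] = tuple(
    name for names in FEATURE_CLASSES.values() for name in names
)

#: The six-term interpretable signature: five stability-selected features
#: plus whole-lesion volume (cm^3), kept for its clinical recognition.
SIGNATURE_FEATURE_NAMES: tuple[str, ...] = (
    "shape_Maximum2DDiameterColumn",
    "shape_LeastAxisLength",
    "shape_Elongation",
    "glcm_Idmn",
    "glcm_DifferenceEntropy",
    "volume_cm3",
)


@dataclass(frozen=True)
class ExtractionConfig:
    """Settings shared by all feature extractions."""

    resegmentation_range_hu: tuple[float, float] = DEFAULT_RESEGMENTATION_RANGE_HU
    fd_fallback_bin_width: float = FD_FALLBACK_BIN_WIDTH_HU
    gldm_alpha: int = 0


def extract_all(
    volume: CTVolume, mask: np.ndarray, config: ExtractionConfig | None = None
) -> dict[str, float]:
    """Extract the full 107-feature vector for one lesion.

    Returns an ordered mapping following :data:`ALL_FEATURE_NAMES`.
    """
    config = config or ExtractionConfig()
    m = check_mask(mask, volume)
    feats: dict[str, float] = {}
    try:
        feats.update(compute_shape_features(m, volume.voxel_spacing_mm))

        reseg = resegment(volume, m, config.resegmentation_range_hu)
        values = volume.intensities[reseg]
        spec = build_discretization(
            values, config.resegmentation_range_hu, config.fd_fallback_bin_width
        )
        levels = discretize(volume, reseg, spec)

        feats.update(
            compute_first_order(values, levels[reseg], volume.voxel_volume_mm3)
        )
        feats.update(compute_glcm_features(levels, reseg, spec.n_levels))
        feats.update(compute_glrlm_features(levels, reseg, spec.n_levels))
        feats.update(compute_glszm_features(levels, reseg, spec.n_levels))
        feats.update(compute_gldm_features(levels, reseg, spec.n_levels, config.gldm_alpha))
        feats.update(compute_ngtdm_features(levels, reseg, spec.n_levels))
    except Exception as exc:  # add feature-stage context, keep the cause
        raise RuntimeError(f"feature extraction failed: {exc}") from exc
    return {name: feats[name] for name in ALL_FEATURE_NAMES}


def compute_signature(
    volume: CTVolume, mask: np.ndarray, config: ExtractionConfig | None = None
) -> dict[str, float]:
    """The six signature values; identical to the matching entries of
    :func:`extract_all` plus whole-lesion volume in cm^3."""
    feats = extract_all(volume, mask, config)
    out = {name: feats[name] for name in SIGNATURE_FEATURE_NAMES if name in feats}
    out["volume_cm3"] = lesion_volume(mask, volume.voxel_spacing_mm)
    return {name: out[name] for name in SIGNATURE_FEATURE_NAMES}
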