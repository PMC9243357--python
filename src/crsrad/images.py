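"""Containers and I/O for CT volumes and lesion masks.

Arrays follow the ``(slice, row, column)`` axis convention: axis 0 is the
supero-inferior (slice) direction, axis 1 the antero-posterior (row)
direction and axis 2 the left-right (column) direction. ``voxel_spacing_mm``
is ordered the same way.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "CTVolume",
    "load_volume",
    "load_mask",
    "save_volume",
    "save_mask",
]


@dataclass(frozen=True)
class CTVolume:
    """A 3D CT image in Hounsfield units with its voxel spacing."""

    intensities: np.ndarray
    voxel_spacing_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities, dtype=float)
        if arr.ndim != 3:
            raise ValueError("CT volume must be a 3D array")
        if not np.all(np.isfinite(arr)):
            raise ValueError("CT intensities must be finite")
        sp = tuple(float(s) for s in self.voxel_spacing_mm)
        if len(sp) != 3 or any(s <= 0 for s in sp):
            raise ValueError("voxel spacing must be three positive lengths")
        object.__setattr__(self, "intensities", arr)
        object.__setattr__(self, "voxel_spacing_mm", sp)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_spacing_mm))


def check_mask(mask: np.ndarray, volume: CTVolume | None = None) -> np.ndarray:
    """Validate a binary lesion mask and return it as a boolean array."""
    m = np.asarray(mask)
    if m.ndim != 3:
        raise ValueError("mask must be a 3D array")
    if m.dtype != bool:
        vals = np.unique(m)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("mask must be binary")
        m = m.astype(bool)
    if volume is not None and m.shape != volume.shape:
        raise ValueError(
            f"mask shape {m.shape} does not match volume shape {volume.shape}"
        )
    return m


def _affine(spacing: tuple[float, float, float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def save_volume(volume: CTVolume, path: str | Path) -> None:
    img = nib.Nifti1Image(
        np.asarray(volume.intensities, dtype=np.float32), _affine(volume.voxel_spacing_mm)
    )
    nib.save(img, str(path))


def save_mask(mask: np.ndarray, spacing: tuple[float, float, float], path: str | Path) -> None:
    img = nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), _affine(spacing))
    nib.save(img, str(path))


def load_volume(path: str | Path) -> CTVolume:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return CTVolume(np.asarray(img.dataobj, dtype=float), spacing)  # type: ignore[arg-type]


def load_mask(path: str | Path) -> np.ndarray:
    img = nib.load(str(path))
    return np.asarray(img.dataobj) > 0.5
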