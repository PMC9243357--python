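"""Shared lattice machinery for the texture-matrix builders."""

from __future__ import annotations

import numpy as np

#: The 13 unique 3D directions (half of the 26-neighborhood, up to sign).
DIRECTIONS_13: tuple[tuple[int, int, int], ...] = tuple(
    (dz, dy, dx)
    for dz in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dx in (-1, 0, 1)
    if (dz, dy, dx) > (0, 0, 0)
)

#: All 26 neighbor offsets.
OFFSETS_26: tuple[tuple[int, int, int], ...] = tuple(
    (dz, dy, dx)
    for dz in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dx in (-1, 0, 1)
    if (dz, dy, dx) != (0, 0, 0)
)


def shifted_pairs(levels: np.ndarray, mask: np.ndarray, offset: tuple[int, int, int]):
    """Gray levels of all in-mask voxel pairs separated by ``offset``.

    Returns two aligned 1D arrays (levels at p, levels at p+offset) over all
    positions where both endpoints lie inside the mask.
    """
    sl_a, sl_b = [], []
    for d in offset:
        if d == 0:
            sl_a.append(slice(None))
            sl_b.append(slice(None))
        elif d > 0:
            sl_a.append(slice(None, -d))
            sl_b.append(slice(d, None))
        else:
            sl_a.append(slice(-d, None))
            sl_b.append(slice(None, d))
    sl_a, sl_b = tuple(sl_a), tuple(sl_b)
    both = mask[sl_a] & mask[sl_b]
    return levels[sl_a][both], levels[sl_b][both]


def runs_along_direction(
    levels: np.ndarray, mask: np.ndarray, direction: tuple[int, int, int]
):
    """Enumerate gray-level runs of in-mask voxels along one lattice direction.

    A run is a maximal set of consecutive voxels (step = ``direction``) inside
    the mask sharing the same gray level. Returns ``(gray, length)`` arrays,
    one entry per run. Vectorized: voxels are keyed by the invariants of the
    line they lie on and sorted by their position along it.
    """
    coords = np.argwhere(mask)
    if len(coords) == 0:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    d = np.asarray(direction)
    nz = np.nonzero(d)[0]
    # position along the line advances by 1 per step in each nonzero axis
    pos = coords[:, nz[0]] * d[nz[0]]
    keys = [coords[:, ax] for ax in range(3) if d[ax] == 0]
    keys += [coords[:, ax] * d[ax] - pos for ax in nz[1:]]
    if not keys:
        keys = [np.zeros(len(coords), dtype=int)]
    order = np.lexsort([pos] + keys[::-1])
    key_mat = np.stack(keys, axis=1)[order]
    pos_s = pos[order]
    gray = levels[tuple(coords[order].T)]
    same_line = np.all(key_mat[1:] == key_mat[:-1], axis=1)
    contiguous = pos_s[1:] == pos_s[:-1] + 1
    same_run = same_line & contiguous & (gray[1:] == gray[:-1])
    starts = np.flatnonzero(np.concatenate(([True], ~same_run)))
    lengths = np.diff(np.append(starts, len(gray)))
    return gray[starts], lengths
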