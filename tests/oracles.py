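"""Independent brute-force oracles used by the test suite.

Each oracle re-derives a quantity by direct enumeration (nested Python
loops, exhaustive search), deliberately sharing no code path with the
package implementation it checks.
"""

from __future__ import annotations

import numpy as np

NEIGHBORS_26 = [
    (dz, dy, dx)
    for dz in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dx in (-1, 0, 1)
    if (dz, dy, dx) != (0, 0, 0)
]

DIRECTIONS_13 = [off for off in NEIGHBORS_26 if off > (0, 0, 0)]


def brute_glcm(levels, mask, n_levels, direction):
    """Symmetric normalized co-occurrence matrix by explicit pair listing."""
    counts = np.zeros((n_levels, n_levels))
    Z, Y, X = levels.shape
    dz, dy, dx = direction
    for z in range(Z):
        for y in range(Y):
            for x in range(X):
                z2, y2, x2 = z + dz, y + dy, x + dx
                if not (0 <= z2 < Z and 0 <= y2 < Y and 0 <= x2 < X):
                    continue
                if mask[z, y, x] and mask[z2, y2, x2]:
                    a, b = levels[z, y, x], levels[z2, y2, x2]
                    counts[a - 1, b - 1] += 1
                    counts[b - 1, a - 1] += 1
    total = counts.sum()
    return counts / total if total > 0 else counts


def brute_runs(levels, mask, direction):
    """All maximal same-level runs along a direction, by walking each line."""
    Z, Y, X = levels.shape
    dz, dy, dx = direction
    runs = []
    visited = set()
    for z in range(Z):
        for y in range(Y):
            for x in range(X):
                # walk only from line starts (previous cell outside the grid)
                pz, py, px = z - dz, y - dy, x - dx
                if 0 <= pz < Z and 0 <= py < Y and 0 <= px < X:
                    continue
                cz, cy, cx = z, y, x
                current = None
                length = 0
                while 0 <= cz < Z and 0 <= cy < Y and 0 <= cx < X:
                    if mask[cz, cy, cx]:
                        g = levels[cz, cy, cx]
                        if current == g:
                            length += 1
                        else:
                            if current is not None:
                                runs.append((current, length))
                            current, length = g, 1
                    else:
                        if current is not None:
                            runs.append((current, length))
                        current, length = None, 0
                    cz, cy, cx = cz + dz, cy + dy, cx + dx
                if current is not None:
                    runs.append((current, length))
    return runs


def brute_zones(levels, mask):
    """Connected zones (26-connectivity, equal level) by flood fill."""
    Z, Y, X = levels.shape
    seen = np.zeros_like(mask, dtype=bool)
    zones = []
    for z in range(Z):
        for y in range(Y):
            for x in range(X):
                if not mask[z, y, x] or seen[z, y, x]:
                    continue
                g = levels[z, y, x]
                stack = [(z, y, x)]
                seen[z, y, x] = True
                size = 0
                while stack:
                    cz, cy, cx = stack.pop()
                    size += 1
                    for dz, dy, dx in NEIGHBORS_26:
                        nz, ny, nx = cz + dz, cy + dy, cx + dx
                        if not (0 <= nz < Z and 0 <= ny < Y and 0 <= nx < X):
                            continue
                        if mask[nz, ny, nx] and not seen[nz, ny, nx] and levels[nz, ny, nx] == g:
                            seen[nz, ny, nx] = True
                            stack.append((nz, ny, nx))
                zones.append((g, size))
    return zones


def brute_dependence(levels, mask, alpha=0):
    """Per-voxel dependence sizes (center + matching 26-neighbors)."""
    Z, Y, X = levels.shape
    out = []
    for z in range(Z):
        for y in range(Y):
            for x in range(X):
                if not mask[z, y, x]:
                    continue
                dep = 1
                for dz, dy, dx in NEIGHBORS_26:
                    nz, ny, nx = z + dz, y + dy, x + dx
                    if not (0 <= nz < Z and 0 <= ny < Y and 0 <= nx < X):
                        continue
                    if mask[nz, ny, nx] and abs(int(levels[z, y, x]) - int(levels[nz, ny, nx])) <= alpha:
                        dep += 1
                out.append((levels[z, y, x], dep))
    return out


def brute_ngtdm(levels, mask, n_levels):
    """(n_i, s_i) from explicit neighborhood means."""
    Z, Y, X = levels.shape
    n_i = np.zeros(n_levels)
    s_i = np.zeros(n_levels)
    for z in range(Z):
        for y in range(Y):
            for x in range(X):
                if not mask[z, y, x]:
                    continue
                vals = []
                for dz, dy, dx in NEIGHBORS_26:
                    nz, ny, nx = z + dz, y + dy, x + dx
                    if 0 <= nz < Z and 0 <= ny < Y and 0 <= nx < X and mask[nz, ny, nx]:
                        vals.append(levels[nz, ny, nx])
                g = levels[z, y, x]
                n_i[g - 1] += 1
                if vals:
                    s_i[g - 1] += abs(g - float(np.mean(vals)))
    return n_i, s_i


def pairwise_auc(scores, labels):
    """AUC as exhaustive pairwise concordance with ties counted 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))


def brute_threshold(scores, labels):
    """Exhaustive G-mean maximization over all midpoint thresholds."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(scores)
    best_tau, best_g = None, -1.0
    for tau in (uniq[:-1] + uniq[1:]) / 2.0:
        pred = scores >= tau
        sens = (pred & (labels == 1)).sum() / (labels == 1).sum()
        spec = (~pred & (labels == 0)).sum() / (labels == 0).sum()
        g = np.sqrt(sens * spec)
        if g > best_g + 1e-15:
            best_g, best_tau = g, tau
    return best_tau, best_g


def greedy_redundancy(X, y, rho_threshold, auc_fn, spearman_fn):
    """Naive re-implementation of the greedy redundancy-collapse procedure."""
    names = list(X.columns)
    alive = set(names)
    while True:
        best = None
        live = sorted(alive)
        for i, a in enumerate(live):
            for b in live[i + 1 :]:
                r = abs(spearman_fn(X[a], X[b]))
                if r < rho_threshold:
                    continue
                if best is None or r > best[0]:
                    best = (r, a, b)
        if best is None:
            break
        _, a, b = best
        auc_a, auc_b = auc_fn(X[a], y), auc_fn(X[b], y)
        if auc_a > auc_b:
            alive.discard(b)
        elif auc_b > auc_a:
            alive.discard(a)
        else:
            alive.discard(max(a, b))
    return [n for n in names if n in alive]
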