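"""Shared helpers for the test suite."""

from __future__ import annotations

import numpy as np


def dice(a: np.ndarray, b: np.ndarray) -> float:
    a = a.astype(bool)
    b = b.astype(bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * float((a & b).sum()) / float(denom)


def match_components(true_labels: np.ndarray, found_labels: np.ndarray) -> dict[int, tuple[int, float]]:
    """For each true label id, the best-overlapping found id and its Dice."""
    out = {}
    true_sizes = np.bincount(true_labels.ravel())
    found_sizes = np.bincount(found_labels.ravel())
    for t in range(1, int(true_labels.max()) + 1):
        overlap = found_labels[true_labels == t]
        overlap = overlap[overlap > 0]
        if overlap.size == 0:
            out[t] = (0, 0.0)
            continue
        ids, counts = np.unique(overlap, return_counts=True)
        f = int(ids[np.argmax(counts)])
        inter = int(counts.max())
        out[t] = (f, 2.0 * inter / (true_sizes[t] + found_sizes[f]))
    return out


def digital_ball(radius_vox: int, pad: int = 4) -> np.ndarray:
    """Boolean digital ball: voxels with centre distance <= radius."""
    n = 2 * (radius_vox + pad) + 1
    c = (n - 1) / 2
    z, y, x = np.mgrid[0:n, 0:n, 0:n]
    return (z - c) ** 2 + (y - c) ** 2 + (x - c) ** 2 <= radius_vox**2


def digital_ellipsoid(semi_axes, pad: int = 4) -> np.ndarray:
    a, b, c = semi_axes
    n = 2 * (int(max(semi_axes)) + pad) + 1
    ctr = (n - 1) / 2
    z, y, x = np.mgrid[0:n, 0:n, 0:n]
    return ((z - ctr) / a) ** 2 + ((y - ctr) / b) ** 2 + ((x - ctr) / c) ** 2 <= 1.0


def flood_fill_count(mask: np.ndarray) -> int:
    """Brute-force 26-connected component count via BFS flood fill."""
    remaining = {tuple(p) for p in np.argwhere(mask)}
    shifts = [
        (dz, dy, dx)
        for dz in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dx in (-1, 0, 1)
        if (dz, dy, dx) != (0, 0, 0)
    ]
    n = 0
    while remaining:
        n += 1
        frontier = [remaining.pop()]
        while frontier:
            z, y, x = frontier.pop()
            for dz, dy, dx in shifts:
                q = (z + dz, y + dy, x + dx)
                if q in remaining:
                    remaining.remove(q)
                    frontier.append(q)
    return n
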