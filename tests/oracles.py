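"""Independent brute-force oracles used to validate pipeline operators.

Everything here is deliberately naive — dense window scans, KD-tree
nearest-background searches, exhaustive enumerations — and shares no code
with the implementations under test.
"""

from __future__ import annotations

import itertools

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.spatial import cKDTree


def _pad_symmetric(arr: np.ndarray, radii: tuple[int, ...]) -> np.ndarray:
    return np.pad(arr, [(r, r) for r in radii], mode="symmetric")


def box_min_filter(arr: np.ndarray, size_zyx: tuple[int, int, int]) -> np.ndarray:
    """Dense window-scan erosion with edge-replicating boundaries."""
    radii = tuple(s // 2 for s in size_zyx)
    padded = _pad_symmetric(arr, radii)
    win = sliding_window_view(padded, size_zyx)
    return win.min(axis=(-3, -2, -1))


def box_max_filter(arr: np.ndarray, size_zyx: tuple[int, int, int]) -> np.ndarray:
    radii = tuple(s // 2 for s in size_zyx)
    padded = _pad_symmetric(arr, radii)
    win = sliding_window_view(padded, size_zyx)
    return win.max(axis=(-3, -2, -1))


def tophat_bruteforce(arr: np.ndarray, size_zyx: tuple[int, int, int]) -> np.ndarray:
    """White top-hat as input minus (erosion then dilation)."""
    opened = box_max_filter(box_min_filter(arr, size_zyx), size_zyx)
    return arr - opened


def gaussian_bruteforce(arr: np.ndarray, sigma_zyx: tuple[float, float, float],
                        truncate: float = 4.0) -> np.ndarray:
    """Dense separable Gaussian convolution with edge-replicating padding."""
    out = np.asarray(arr, dtype=np.float64)
    for axis, sigma in enumerate(sigma_zyx):
        if sigma == 0:
            continue
        radius = int(truncate * sigma + 0.5)
        x = np.arange(-radius, radius + 1, dtype=np.float64)
        kernel = np.exp(-(x**2) / (2 * sigma**2))
        kernel /= kernel.sum()
        moved = np.moveaxis(out, axis, -1)
        padded = np.pad(moved, [(0, 0)] * (moved.ndim - 1) + [(radius, radius)],
                        mode="symmetric")
        conv = np.apply_along_axis(
            lambda v: np.convolve(v, kernel, mode="valid"), -1, padded)
        out = np.moveaxis(conv, -1, axis)
    return out


def edt_distances_bruteforce(mask: np.ndarray) -> np.ndarray:
    """Per-foreground-voxel distance to the nearest background voxel.

    Nearest-neighbour search over all background coordinates (KD-tree),
    independent of the distance-transform algorithm under test.  Returns
    +inf where there is no background.
    """
    mask = np.asarray(mask, dtype=bool)
    out = np.zeros(mask.shape, dtype=float)
    bg = np.argwhere(~mask)
    fg = np.argwhere(mask)
    if len(bg) == 0:
        out[mask] = np.inf
        return out
    tree = cKDTree(bg)
    d, _ = tree.query(fg)
    out[tuple(fg.T)] = d
    return out


def mannwhitney_exact_enumeration(a, b) -> float:
    """Two-sided exact Mann-Whitney p by full assignment enumeration.

    Enumerates every way of assigning the pooled observations to the two
    groups and counts assignments whose U statistic is at least as far
    from its null mean as the observed one.
    """
    a, b = list(a), list(b)
    pooled = a + b
    n1 = len(a)

    def ustat(group_a, group_b):
        return sum(1 for x in group_a for y in group_b if x > y) \
            + 0.5 * sum(1 for x in group_a for y in group_b if x == y)

    u_obs = ustat(a, b)
    center = n1 * len(b) / 2.0
    hits = total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        ga = [pooled[i] for i in idx]
        gb = [pooled[i] for i in range(len(pooled)) if i not in idx]
        total += 1
        if abs(ustat(ga, gb) - center) >= abs(u_obs - center) - 1e-12:
            hits += 1
    return hits / total


def kruskal_h_bruteforce(groups: list[list[float]]) -> float:
    """Kruskal-Wallis H from first principles (mid-ranks, tie correction)."""
    pooled = [x for g in groups for x in g]
    n = len(pooled)
    order = sorted(range(n), key=lambda i: pooled[i])
    ranks = [0.0] * n
    i = 0
    while i < n:
        j = i
        while j < n and pooled[order[j]] == pooled[order[i]]:
            j += 1
        midrank = (i + j + 1) / 2.0
        for k in range(i, j):
            ranks[order[k]] = midrank
        i = j
    start = 0
    h = 0.0
    for g in groups:
        r = sum(ranks[start:start + len(g)])
        h += r * r / len(g)
        start += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    # tie correction
    _, counts = np.unique(pooled, return_counts=True)
    correction = 1 - float((counts**3 - counts).sum()) / (n**3 - n)
    return h / correction


def label_slices_bruteforce(mask2d: np.ndarray, eight_connected: bool = True):
    """Flood-fill 2D connected-component labeling."""
    mask2d = np.asarray(mask2d, dtype=bool)
    labels = np.zeros(mask2d.shape, dtype=int)
    offsets = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    if eight_connected:
        offsets += [(-1, -1), (-1, 1), (1, -1), (1, 1)]
    current = 0
    for y, x in np.argwhere(mask2d):
        if labels[y, x]:
            continue
        current += 1
        stack = [(y, x)]
        labels[y, x] = current
        while stack:
            cy, cx = stack.pop()
            for dy, dx in offsets:
                ny, nx = cy + dy, cx + dx
                if (0 <= ny < mask2d.shape[0] and 0 <= nx < mask2d.shape[1]
                        and mask2d[ny, nx] and not labels[ny, nx]):
                    labels[ny, nx] = current
                    stack.append((ny, nx))
        current = labels.max()
    return labels, int(labels.max())


def partitions_equal(lab_a: np.ndarray, lab_b: np.ndarray) -> bool:
    """True when two label volumes induce the same partition of foreground."""
    fg_a = lab_a > 0
    fg_b = lab_b > 0
    if not np.array_equal(fg_a, fg_b):
        return False
    pairs = set(zip(lab_a[fg_a].ravel(), lab_b[fg_a].ravel()))
    a_ids = {p[0] for p in pairs}
    b_ids = {p[1] for p in pairs}
    return len(pairs) == len(a_ids) == len(b_ids)
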