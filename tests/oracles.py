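"""Independent brute-force oracles used to verify the implementation.

These deliberately use the slow, obvious definitions (O(W*L) window scans,
breadth-first connected components on an explicit adjacency graph) and
share no code with the package.
"""

from __future__ import annotations

import numpy as np


def brute_window_extreme(row, L: int, origin: int, mode: str) -> np.ndarray:
    """Sliding min/max over windows clipped to the row, by direct scan."""
    row = np.asarray(row)
    W = row.shape[0]
    out = np.empty_like(row)
    fn = min if mode == "min" else max
    for j in range(W):
        lo = max(0, j - origin)
        hi = min(W, j - origin + L)
        vals = [row[k] for k in range(lo, hi)]
        out[j] = fn(vals)
    return out


def brute_erode(row, L: int) -> np.ndarray:
    return brute_window_extreme(row, L, L // 2, "min")


def brute_dilate(row, L: int) -> np.ndarray:
    return brute_window_extreme(row, L, L // 2, "max")


def brute_open(row, L: int) -> np.ndarray:
    return brute_window_extreme(brute_erode(row, L), L, L - 1 - (L // 2), "max")


def brute_pair_erode(mask, axis: str) -> np.ndarray:
    """Binary pair erosion, anchor at first pixel, zero padding."""
    m = np.asarray(mask, dtype=bool)
    out = np.zeros_like(m)
    if m.ndim == 1:
        m = m[None, :]
        out = out[None, :]
    H, W = m.shape
    for i in range(H):
        for j in range(W):
            if axis == "in_row":
                out[i, j] = m[i, j] and (j + 1 < W and m[i, j + 1])
            else:
                out[i, j] = m[i, j] and (i + 1 < H and m[i + 1, j])
    return out.reshape(np.asarray(mask).shape)


def brute_pair_dilate(mask, axis: str) -> np.ndarray:
    m = np.asarray(mask, dtype=bool)
    out = np.zeros_like(m)
    if m.ndim == 1:
        m = m[None, :]
        out = out[None, :]
    H, W = m.shape
    for i in range(H):
        for j in range(W):
            if axis == "in_row":
                out[i, j] = m[i, j] or (j - 1 >= 0 and m[i, j - 1])
            else:
                out[i, j] = m[i, j] or (i - 1 >= 0 and m[i - 1, j])
    return out.reshape(np.asarray(mask).shape)


def bfs_components(mask, m: int = 1, n: int = 1, p: int = 1, q: int = 0):
    """Connected components under the row-labeling adjacency, by BFS.

    Pixel (i, j) is adjacent to (i-1, j-m .. j+n) in the previous row and,
    within its row, to pixels at signed offsets -p..q (symmetrized, i.e.
    reach max(p, q)).  Returns a list of frozensets of (row, col).
    """
    mask = np.asarray(mask, dtype=bool)
    H, W = mask.shape
    pixels = {(i, j) for i in range(H) for j in range(W) if mask[i, j]}
    reach = max(p, q)
    comps = []
    seen = set()
    for start in sorted(pixels):
        if start in seen:
            continue
        comp = set()
        queue = [start]
        seen.add(start)
        while queue:
            i, j = queue.pop()
            comp.add((i, j))
            neighbours = []
            for dj in range(-m, n + 1):
                neighbours.append((i - 1, j + dj))  # previous row
            for dj in range(-n, m + 1):
                neighbours.append((i + 1, j + dj))  # mirror of the above
            for dj in range(-reach, reach + 1):
                if dj:
                    neighbours.append((i, j + dj))
            for nb in neighbours:
                if nb in pixels and nb not in seen:
                    seen.add(nb)
                    queue.append(nb)
        comps.append(frozenset(comp))
    return comps
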