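"""Brute-force reference implementations used only by the test suite.

Each oracle recomputes an operator from its mathematical definition by the
most literal route available (exhaustive search, exact rational arithmetic,
per-pixel double loops, breadth-first flood fill), sharing no code with the
package's implementations.
"""

from __future__ import annotations

from collections import deque
from fractions import Fraction

import numpy as np


def otsu_sweep(pixels: np.ndarray, floor: int = 0) -> int | None:
    """Exhaustive Otsu: evaluate sigma^2_b(t) = w0*w1*(mu0-mu1)^2 with exact
    rational arithmetic for every candidate threshold, ignoring pixels below
    the floor.  Returns the smallest maximizing t, or None if no split."""
    values = pixels.ravel()
    values = values[values >= floor]
    n = len(values)
    if n == 0:
        return None
    best_t, best_score = None, None
    for t in range(floor, 256):
        class0 = values[values <= t]
        class1 = values[values > t]
        w0, w1 = len(class0), len(class1)
        if w0 == 0 or w1 == 0:
            continue
        mu0 = Fraction(int(class0.sum()), w0)
        mu1 = Fraction(int(class1.sum()), w1)
        score = Fraction(w0, n) * Fraction(w1, n) * (mu0 - mu1) ** 2
        if best_score is None or score > best_score:
            best_t, best_score = t, score
    return best_t


def _mirror(i: int, n: int) -> int:
    """Reflect an out-of-range index without repeating the edge pixel."""
    if n == 1:
        return 0
    while not 0 <= i < n:
        i = -i if i < 0 else 2 * (n - 1) - i
    return i


def adaptive_gaussian_direct(
    pixels: np.ndarray, block_size: int, c_offset: int
) -> np.ndarray:
    """Per-pixel double-loop adaptive Gaussian-C mask.

    For each pixel, gathers its mirrored block_size x block_size
    neighbourhood, takes the normalized-Gaussian weighted mean, rounds it
    half-up to an integer, subtracts the offset, and compares."""
    sigma = 0.3 * ((block_size - 1) * 0.5 - 1) + 0.8
    half = (block_size - 1) // 2
    x = np.arange(-half, half + 1, dtype=np.float64)
    g = np.exp(-(x**2) / (2.0 * sigma**2))
    w2d = np.outer(g, g)
    w2d /= w2d.sum()
    h, w = pixels.shape
    mask = np.zeros((h, w), dtype=bool)
    for r in range(h):
        rows = [_mirror(r + dy, h) for dy in range(-half, half + 1)]
        for c in range(w):
            cols = [_mirror(c + dx, w) for dx in range(-half, half + 1)]
            patch = pixels[np.ix_(rows, cols)].astype(np.float64)
            local_mean = float(np.sum(w2d * patch))
            threshold = np.floor(local_mean + 0.5) - c_offset
            mask[r, c] = pixels[r, c] > threshold
    return mask


def flood_fill_labels(mask: np.ndarray, connectivity: int) -> np.ndarray:
    """BFS connected-component labels, numbered in raster order of each
    component's first pixel (same numbering contract as the package)."""
    if connectivity == 4:
        neigh = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        neigh = [(dy, dx) for dy in (-1, 0, 1) for dx in (-1, 0, 1) if (dy, dx) != (0, 0)]
    mask = np.asarray(mask).astype(bool)
    h, w = mask.shape
    labels = np.zeros((h, w), dtype=np.int32)
    current = 0
    for r0 in range(h):
        for c0 in range(w):
            if not mask[r0, c0] or labels[r0, c0]:
                continue
            current += 1
            queue = deque([(r0, c0)])
            labels[r0, c0] = current
            while queue:
                r, c = queue.popleft()
                for dy, dx in neigh:
                    rr, cc = r + dy, c + dx
                    if 0 <= rr < h and 0 <= cc < w and mask[rr, cc] and not labels[rr, cc]:
                        labels[rr, cc] = current
                        queue.append((rr, cc))
    return labels
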