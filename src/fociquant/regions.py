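"""Connected-component labeling and region measurement/filtering.

Both segmentation stages end the same way: a binary mask is decomposed into
connected components, each component is measured (area, bounding box,
centroid), and components are filtered by pixel area — a size gate that
stands in for cell-type selection on the marker channel and for a minimum
focus size on the damage channel.

Labeling is a two-pass run-based union-find: each row of the mask is
reduced to runs of consecutive foreground pixels, runs are unioned with
overlapping runs of the previous row (with a one-column tolerance under
8-connectivity), and final labels are assigned 1..n in raster-scan order of
each component's first pixel, which makes the labeling fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidParameterError


@dataclass(frozen=True)
class Region:
    """One connected component of a binary mask."""

    label: int
    area: int
    bbox: tuple[int, int, int, int]  # (row_min, col_min, row_max, col_max), half-open
    centroid: tuple[float, float]  # (row, col) means of member pixel coordinates


def _row_runs(row: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) column runs of foreground in one mask row."""
    padded = np.empty(row.size + 2, dtype=np.int8)
    padded[0] = padded[-1] = 0
    padded[1:-1] = row
    diff = np.diff(padded)
    starts = np.flatnonzero(diff == 1)
    stops = np.flatnonzero(diff == -1)
    return list(zip(starts.tolist(), stops.tolist()))


class _UnionFind:
    __slots__ = ("parent",)

    def __init__(self) -> None:
        self.parent: list[int] = []

    def make(self) -> int:
        self.parent.append(len(self.parent))
        return len(self.parent) - 1

    def find(self, x: int) -> int:
        parent = self.parent
        root = x
        while parent[root] != root:
            root = parent[root]
        while parent[x] != root:  # path compression
            parent[x], x = root, parent[x]
        return root

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            # attach the younger root to the older so roots stay raster-minimal
            if ra < rb:
                self.parent[rb] = ra
            else:
                self.parent[ra] = rb


def label_components(
    mask: np.ndarray, connectivity: int = 8
) -> tuple[np.ndarray, list[Region]]:
    """Label the connected components of a binary mask.

    Returns ``(labels, regions)`` where ``labels`` is an int32 array with 0
    for background and components numbered 1..n in raster-scan order of
    their first pixel, and ``regions`` lists one :class:`Region` per
    component, sorted by label.
    """
    if connectivity not in (4, 8):
        raise InvalidParameterError(f"connectivity must be 4 or 8, got {connectivity}")
    mask = np.asarray(mask).astype(bool)
    if mask.ndim != 2:
        raise InvalidParameterError(f"mask must be 2-D, got shape {mask.shape}")
    h, w = mask.shape
    labels = np.zeros((h, w), dtype=np.int32)

    uf = _UnionFind()
    runs: list[tuple[int, int, int, int]] = []  # (row, start, stop, run_id)
    prev: list[tuple[int, int, int]] = []  # (start, stop, run_id) of previous row
    for r in range(h):
        cur: list[tuple[int, int, int]] = []
        for c0, c1 in _row_runs(mask[r]):
            rid = uf.make()
            runs.append((r, c0, c1, rid))
            for p0, p1, pid in prev:
                if connectivity == 8:
                    touching = c0 <= p1 and p0 <= c1
                else:
                    touching = c0 < p1 and p0 < c1
                if touching:
                    uf.union(rid, pid)
            cur.append((c0, c1, rid))
        prev = cur

    # final labels in raster order of each component's first run
    root_to_label: dict[int, int] = {}
    for _, _, _, rid in runs:
        root = uf.find(rid)
        if root not in root_to_label:
            root_to_label[root] = len(root_to_label) + 1

    n = len(root_to_label)
    area = np.zeros(n + 1, dtype=np.int64)
    row_sum = np.zeros(n + 1, dtype=np.float64)
    col_sum = np.zeros(n + 1, dtype=np.float64)
    rmin = np.full(n + 1, h, dtype=np.int64)
    rmax = np.zeros(n + 1, dtype=np.int64)
    cmin = np.full(n + 1, w, dtype=np.int64)
    cmax = np.zeros(n + 1, dtype=np.int64)
    for r, c0, c1, rid in runs:
        lab = root_to_label[uf.find(rid)]
        labels[r, c0:c1] = lab
        length = c1 - c0
        area[lab] += length
        row_sum[lab] += r * length
        col_sum[lab] += (c0 + c1 - 1) * length / 2.0
        rmin[lab] = min(rmin[lab], r)
        rmax[lab] = max(rmax[lab], r + 1)
        cmin[lab] = min(cmin[lab], c0)
        cmax[lab] = max(cmax[lab], c1)

    regions = [
        Region(
            label=lab,
            area=int(area[lab]),
            bbox=(int(rmin[lab]), int(cmin[lab]), int(rmax[lab]), int(cmax[lab])),
            centroid=(row_sum[lab] / area[lab], col_sum[lab] / area[lab]),
        )
        for lab in range(1, n + 1)
    ]
    return labels, regions


def filter_by_area(
    regions: list[Region], min_area: int, max_area: int | None = None
) -> list[Region]:
    """Keep regions whose pixel area lies in [min_area, max_area].

    ``max_area=None`` means unbounded above (the focus-size gate); nucleus
    gating uses a bounded window.  Order is preserved.
    """
    if min_area < 1:
        raise InvalidParameterError(f"min_area must be >= 1, got {min_area}")
    if max_area is not None and max_area < min_area:
        raise InvalidParameterError(
            f"max_area ({max_area}) must be >= min_area ({min_area})"
        )
    hi = np.inf if max_area is None else max_area
    return [reg for reg in regions if min_area <= reg.area <= hi]


def marker_size_histogram(
    regions_per_image: list[list[Region]], bin_width: int = 100
) -> tuple[np.ndarray, np.ndarray]:
    """Area-frequency histogram over all detected marker objects.

    Returns ``(bin_edges, counts)`` with bins ``[k*bin_width, (k+1)*bin_width)``
    covering all observed areas; both arrays are empty when no regions exist.
    """
    if bin_width < 1:
        raise InvalidParameterError(f"bin_width must be >= 1, got {bin_width}")
    areas = [reg.area for regs in regions_per_image for reg in regs]
    if not areas:
        return np.array([], dtype=np.int64), np.array([], dtype=np.int64)
    n_bins = max(areas) // bin_width + 1
    edges = np.arange(n_bins + 1, dtype=np.int64) * bin_width
    counts = np.bincount(np.asarray(areas) // bin_width, minlength=n_bins)
    return edges, counts.astype(np.int64)
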