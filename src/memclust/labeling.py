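"""Connected-component labeling of occupancy grids.

Implements the Hoshen-Kopelman algorithm: a single raster-order sweep over
the occupied sites with union-find bookkeeping of label equivalences, the
standard labeling method of percolation analysis.  Unlike generic image
labelers it supports periodic boundary conditions, which the lattice
simulator needs (the membrane is modelled as a torus), and both 4- and
8-neighbor connectivity.

The output is a :class:`ClusterLabeling`: an integer grid in which ``0``
marks empty sites and each cluster carries a label from the contiguous
range ``1..K``, plus the per-cluster site counts ``A_i`` that feed the
cluster-size distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ClusterLabeling", "label_clusters"]

# neighbors already visited in raster (row-major) order
_SCAN_OFFSETS = {
    4: ((0, -1), (-1, 0)),
    8: ((0, -1), (-1, -1), (-1, 0), (-1, 1)),
}
_FULL_OFFSETS = {
    4: ((0, -1), (0, 1), (-1, 0), (1, 0)),
    8: tuple(
        (di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1) if (di, dj) != (0, 0)
    ),
}


@dataclass(frozen=True)
class ClusterLabeling:
    """Labeled occupancy grid.

    Attributes
    ----------
    labels:
        2D int array; 0 = empty, k >= 1 = cluster id.
    sizes:
        ``sizes[k - 1]`` is the number of sites in cluster ``k``.
    """

    labels: np.ndarray
    sizes: np.ndarray

    def __post_init__(self) -> None:
        if self.labels.ndim != 2:
            raise ValueError("labels must be a 2D grid")
        occupied = int(np.count_nonzero(self.labels))
        if occupied != int(self.sizes.sum()):
            raise ValueError("cluster sizes do not sum to the occupied site count")

    @property
    def n_clusters(self) -> int:
        return int(len(self.sizes))


def _find(parent: np.ndarray, x: int) -> int:
    # iterative find with path compression
    root = x
    while parent[root] != root:
        root = parent[root]
    while parent[x] != root:
        parent[x], x = root, parent[x]
    return root


def _union(parent: np.ndarray, a: int, b: int) -> int:
    ra, rb = _find(parent, a), _find(parent, b)
    if ra == rb:
        return ra
    # deterministic: smaller provisional label wins
    if rb < ra:
        ra, rb = rb, ra
    parent[rb] = ra
    return ra


def label_clusters(
    mask: np.ndarray, connectivity: int = 8, periodic: bool = False
) -> ClusterLabeling:
    """Label connected clusters of occupied sites.

    Parameters
    ----------
    mask:
        2D boolean (or truthy) occupancy grid.
    connectivity:
        4 (edge-sharing neighbors) or 8 (edges and diagonals).
    periodic:
        If True, clusters wrap across opposite edges (toroidal topology).

    Returns
    -------
    ClusterLabeling
        Labels form the contiguous range ``1..K`` in raster order of first
        appearance; two occupied sites adjacent under the chosen
        connectivity always share a label.
    """
    grid = np.asarray(mask)
    if grid.ndim != 2 or grid.size == 0:
        raise ValueError("mask must be a non-empty 2D grid")
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    occ = grid.astype(bool)
    h, w = occ.shape

    labels = np.zeros((h, w), dtype=np.int64)
    # parent[0] is a sentinel for "empty"
    parent = np.zeros(occ.sum() + 1, dtype=np.int64)
    next_label = 1
    scan = _SCAN_OFFSETS[connectivity]

    rows, cols = np.nonzero(occ)  # raster order (row-major)
    for i, j in zip(rows.tolist(), cols.tolist()):
        assigned = 0
        for di, dj in scan:
            ni, nj = i + di, j + dj
            if ni < 0 or nj < 0 or nj >= w:
                continue
            lab = labels[ni, nj]
            if lab:
                assigned = lab if not assigned else _union(parent, assigned, lab)
        if not assigned:
            parent[next_label] = next_label
            assigned = next_label
            next_label += 1
        labels[i, j] = assigned

    if periodic and (h > 1 or w > 1):
        full = _FULL_OFFSETS[connectivity]
        border = [
            (i, j)
            for i, j in zip(rows.tolist(), cols.tolist())
            if i == 0 or i == h - 1 or j == 0 or j == w - 1
        ]
        for i, j in border:
            for di, dj in full:
                ni, nj = i + di, j + dj
                if 0 <= ni < h and 0 <= nj < w:
                    continue  # already handled in the main sweep
                ni %= h
                nj %= w
                lab = labels[ni, nj]
                if lab:
                    _union(parent, labels[i, j], lab)

    # canonicalize: contiguous labels 1..K in order of first appearance
    remap = np.zeros(next_label, dtype=np.int64)
    out = np.zeros_like(labels)
    k = 0
    sizes: list[int] = []
    for i, j in zip(rows.tolist(), cols.tolist()):
        root = _find(parent, labels[i, j])
        if remap[root] == 0:
            k += 1
            remap[root] = k
            sizes.append(0)
        lab = remap[root]
        out[i, j] = lab
        sizes[lab - 1] += 1

    return ClusterLabeling(labels=out, sizes=np.asarray(sizes, dtype=np.int64))
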