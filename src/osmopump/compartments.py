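"""Solvent-bin clustering under periodic boundaries and compartment roles.

The solvent bins of a labelled grid are grouped into connected components
under strict 6-connectivity (face adjacency), with wrapping across all
three periodic boundaries so a compartment split over the box faces is
identified as one cluster. For a closed membrane (vesicle, double
bilayer) this yields exactly two clusters: the bulk ("outer")
compartment, recognised as the cluster owning the most of the eight box
corner bins, and the enclosed ("inner") compartment. A single cluster
for a system that should enclose solvent signals membrane rupture.

Cluster ids are deterministic: clusters are numbered 0, 1, 2, ... by the
first bin they touch in a lexicographic (C-order) scan of the grid.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .errors import AmbiguousOuterError, InputError, StateError
from .grid import SOLVENT, BinContents, BinLabels, GridSpec

#: cluster_id sentinel carried by membrane bins
MEMBRANE_SENTINEL = -1


@dataclass(frozen=True)
class CompartmentMap:
    """Partition of the solvent bins into PBC-connected clusters.

    ``cluster_id`` has the grid's shape; solvent bins carry their cluster
    id (0-based), membrane bins carry :data:`MEMBRANE_SENTINEL`.
    ``outer_id``/``inner_id`` are filled by :func:`assign_roles` (inner is
    defined only for exactly two clusters).
    """

    cluster_id: np.ndarray
    n_clusters: int
    grid: GridSpec
    outer_id: int | None = None
    inner_id: int | None = None

    @property
    def cluster_sizes(self) -> np.ndarray:
        """Number of bins per cluster, indexed by cluster id."""
        ids = self.cluster_id[self.cluster_id != MEMBRANE_SENTINEL]
        return np.bincount(ids, minlength=self.n_clusters)


def periodic_label(mask: np.ndarray) -> tuple[np.ndarray, int]:
    """6-connected components of a boolean field with periodic wrapping.

    Uses a plain (non-periodic) connected-component pass, then merges
    labels that touch across opposite faces with a union-find, and finally
    renumbers components 0..k-1 in order of first appearance in a C-order
    scan. Background cells get -1.
    """
    structure = ndimage.generate_binary_structure(3, 1)  # faces only
    lab, n = ndimage.label(mask, structure=structure)
    if n == 0:
        return np.full(mask.shape, -1, dtype=np.int64), 0

    parent = np.arange(n + 1, dtype=np.int64)

    def find(x: int) -> int:
        root = x
        while parent[root] != root:
            root = parent[root]
        while parent[x] != root:  # path compression
            parent[x], x = root, parent[x]
        return root

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    for axis in range(3):
        lo = np.take(lab, 0, axis=axis).ravel()
        hi = np.take(lab, -1, axis=axis).ravel()
        both = (lo > 0) & (hi > 0)
        for a, b in {(int(a), int(b)) for a, b in zip(lo[both], hi[both])}:
            union(a, b)

    root = np.array([find(i) for i in range(n + 1)], dtype=np.int64)
    merged = root[lab]  # 0 stays background

    # deterministic ids: order roots by first flat occurrence in C-order
    flat = merged.ravel()
    first = np.full(n + 1, flat.size, dtype=np.int64)
    np.minimum.at(first, flat, np.arange(flat.size, dtype=np.int64))
    roots = [r for r in np.unique(root[1:])]
    roots.sort(key=lambda r: first[r])
    remap = np.full(n + 1, -1, dtype=np.int64)
    for new, r in enumerate(roots):
        remap[r] = new
    out = np.where(merged > 0, remap[merged], -1)
    return out, len(roots)


def cluster_solvent(labels: BinLabels) -> CompartmentMap:
    """Cluster the solvent (0-valued) bins under periodic 6-connectivity."""
    solvent_mask = labels.labels == SOLVENT
    if not solvent_mask.any():
        raise InputError("no solvent bins to cluster: every bin is a membrane bin")
    cluster_id, n = periodic_label(solvent_mask)
    return CompartmentMap(cluster_id=cluster_id, n_clusters=n, grid=labels.grid)


def _corner_bins(grid: GridSpec) -> np.ndarray:
    """The (up to 8) distinct corner bin triples of the grid."""
    corners = np.array(
        [
            (i, j, k)
            for i in (0, grid.nx - 1)
            for j in (0, grid.ny - 1)
            for k in (0, grid.nz - 1)
        ]
    )
    return np.unique(corners, axis=0)


def outer_compartment(cmap: CompartmentMap, grid: GridSpec) -> int:
    """Identify the bulk solvent cluster by the corner-bin vote.

    The cluster containing the largest number of the eight box-corner bins
    is the outer (bulk) compartment. Corner bins that happen to be
    membrane bins vote for nobody. A tie — or all corners being membrane —
    means the enclosed object crosses a box corner under PBC; this is a
    hard error, and the cure is recentring the system on the vesicle.
    """
    if cmap.n_clusters < 1:
        raise StateError("no solvent clusters")
    corners = _corner_bins(grid)
    ids = cmap.cluster_id[corners[:, 0], corners[:, 1], corners[:, 2]]
    ids = ids[ids != MEMBRANE_SENTINEL]
    if len(ids) == 0:
        raise AmbiguousOuterError(
            "all corner bins are membrane bins; recentre the system so the "
            "membrane does not cross a box corner"
        )
    votes = np.bincount(ids, minlength=cmap.n_clusters)
    best = int(votes.max())
    winners = np.flatnonzero(votes == best)
    if len(winners) > 1:
        raise AmbiguousOuterError(
            f"corner-bin vote tied between clusters {winners.tolist()} "
            f"({best} corners each); recentre the system on the vesicle"
        )
    return int(winners[0])


def assign_roles(cmap: CompartmentMap, grid: GridSpec) -> CompartmentMap:
    """Return a copy of ``cmap`` with outer_id (and inner_id if 2 clusters) set."""
    outer = outer_compartment(cmap, grid)
    inner = None
    if cmap.n_clusters == 2:
        inner = 1 - outer
    return replace(cmap, outer_id=outer, inner_id=inner)


def detect_rupture(cmap: CompartmentMap) -> bool:
    """True iff a system expected to enclose solvent has a single cluster.

    A pore wide enough for the voxel grid joins the inner and outer
    solvent into one connected compartment; pumping must then stop and a
    healing (no-pumping) run is performed instead.
    """
    return cmap.n_clusters == 1


def count_enclosed_solvent(cmap: CompartmentMap, contents: BinContents) -> int:
    """Number of solvent molecules residing in inner-compartment bins.

    Solvent sitting inside membrane bins keeps the membrane hydrated and
    is excluded from the count (and from pumping).
    """
    if cmap.inner_id is None:
        raise StateError(
            "inner compartment undefined (need exactly 2 clusters with roles assigned)"
        )
    flat_ids = cmap.cluster_id.ravel()[contents.solvent_flat_bins]
    return int(np.count_nonzero(flat_ids == cmap.inner_id))


def compartment_volume(cmap: CompartmentMap, grid: GridSpec, which: int) -> float:
    """Coarse compartment volume: bin count x bin volume, nm^3."""
    if not (0 <= which < cmap.n_clusters):
        raise InputError(f"unknown cluster id {which} (have {cmap.n_clusters})")
    n = int(np.count_nonzero(cmap.cluster_id == which))
    return n * grid.bin_volume
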