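"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately reimplement operations the simplest
possible way (per-particle loops, queue-based flood fill, dense grid
search) so the vectorised implementations are checked against code that
shares nothing with them.
"""

from __future__ import annotations

import math
from collections import deque

import numpy as np
import pytest

import osmopump as op
from osmopump.sysio import ParticleSystem, molecules_from_resids


# ---------------------------------------------------------------------------
# system builders
# ---------------------------------------------------------------------------

def point_system(
    positions,
    box,
    membrane=(),
    solvent=(),
    velocities=None,
    names=None,
) -> ParticleSystem:
    """Ad-hoc system of single-particle molecules with explicit groups."""
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    n = len(positions)
    resids = np.arange(1, n + 1, dtype=np.int64)
    if names is None:
        names = np.array(["X"] * n)
    sys_ = ParticleSystem(
        positions=positions,
        velocities=None if velocities is None else np.asarray(velocities, dtype=float),
        names=np.asarray(names, dtype=str),
        resnames=np.array(["MOL"] * n),
        resids=resids,
        molecules=molecules_from_resids(resids),
        box=op.BoxVec(*box),
        groups={
            "membrane": np.asarray(membrane, dtype=np.int64),
            "solvent": np.asarray(solvent, dtype=np.int64),
        },
    )
    return sys_


def boxed_shell_system(inner_waters=0, inner_ions=0, seed=0):
    """Hollow cubic membrane shell in a 13 nm box (1.3 nm grid = 10^3 bins).

    Membrane particles sit at the centers of all bins of the shell of the
    cube spanning bins [2, 7]^3, enclosing a 4x4x4-bin inner compartment.
    Interior waters/ions are placed at random interior bin centers.
    Returns (system, n_inner_bins).
    """
    rng = np.random.default_rng(seed)
    edge = 1.3
    mem = []
    for i in range(2, 8):
        for j in range(2, 8):
            for k in range(2, 8):
                if i in (2, 7) or j in (2, 7) or k in (2, 7):
                    mem.append(((i + 0.5) * edge, (j + 0.5) * edge, (k + 0.5) * edge))
    inner_bins = [
        (i, j, k) for i in range(3, 7) for j in range(3, 7) for k in range(3, 7)
    ]
    waters, ions = [], []
    for _ in range(inner_waters):
        b = inner_bins[rng.integers(len(inner_bins))]
        waters.append([(c + 0.5) * edge + rng.uniform(-0.3, 0.3) for c in b])
    for _ in range(inner_ions):
        b = inner_bins[rng.integers(len(inner_bins))]
        ions.append([(c + 0.5) * edge + rng.uniform(-0.3, 0.3) for c in b])
    pos = np.array(mem + waters + ions, dtype=float)
    n_mem, n_w = len(mem), len(waters)
    sys_ = point_system(
        pos,
        (13.0, 13.0, 13.0),
        membrane=range(n_mem),
        solvent=range(n_mem, n_mem + n_w),
    )
    return sys_, len(inner_bins)


@pytest.fixture(scope="session")
def vesicle():
    """Default synthetic vesicle (r_mid 6 nm, thickness 2 nm, 20 nm box)."""
    return op.make_vesicle()


@pytest.fixture(scope="session")
def pored_vesicle():
    return op.make_pored_vesicle(pore_radius=3.0)


@pytest.fixture(scope="session")
def double_bilayer():
    return op.make_double_bilayer()


@pytest.fixture()
def make_point_system():
    return point_system


@pytest.fixture()
def make_boxed_shell():
    return boxed_shell_system


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def bfs_flood_fill_pbc(mask: np.ndarray) -> tuple[np.ndarray, int]:
    """Queue-based periodic flood fill over True cells, 6-connectivity.

    Components are numbered by first cell reached in a C-order scan —
    the same deterministic convention the implementation promises.
    """
    shape = mask.shape
    labels = np.full(shape, -1, dtype=np.int64)
    current = 0
    for start in np.ndindex(shape):
        if not mask[start] or labels[start] != -1:
            continue
        queue = deque([start])
        labels[start] = current
        while queue:
            i, j, k = queue.popleft()
            for d in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)):
                nb = ((i + d[0]) % shape[0], (j + d[1]) % shape[1], (k + d[2]) % shape[2])
                if mask[nb] and labels[nb] == -1:
                    labels[nb] = current
                    queue.append(nb)
        current += 1
    return labels, current


def brute_force_label_bins(positions, membrane_idx, box, grid_shape):
    """Per-particle loop binning membrane particles (label_bins oracle)."""
    labels = np.zeros(grid_shape, dtype=np.int8)
    box = np.asarray(box, dtype=float)
    edges = box / np.asarray(grid_shape)
    for p in np.asarray(positions)[np.asarray(membrane_idx, dtype=int)]:
        wrapped = p - np.floor(p / box) * box
        # floor of the rounded quotient, the stated binning convention
        # (float `//` can differ by one ulp at exact bin boundaries)
        ijk = tuple(
            min(int(math.floor(wrapped[a] / edges[a])), grid_shape[a] - 1) for a in range(3)
        )
        labels[ijk] = 1
    return labels


def dense_grid_best_insertion(grid, target_bin, nearby, margin, steps=30):
    """Exhaustive grid search for the max-min-distance insertion point."""
    lo = grid.bin_lower_corner(target_bin) + margin
    hi = grid.bin_lower_corner(target_bin) + grid.edges - margin
    axes = [np.linspace(lo[a], hi[a], steps) for a in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    box = grid.box.as_array()
    best_d, best_p = -1.0, None
    nearby = np.asarray(nearby)
    for p in pts:
        diff = p - nearby
        diff -= np.round(diff / box) * box
        d = math.sqrt((diff**2).sum(axis=1).min())
        if d > best_d:
            best_d, best_p = d, p
    return best_p, best_d


@pytest.fixture()
def flood_fill_oracle():
    return bfs_flood_fill_pbc


@pytest.fixture()
def label_bins_oracle():
    return brute_force_label_bins


@pytest.fixture()
def insertion_oracle():
    return dense_grid_best_insertion
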