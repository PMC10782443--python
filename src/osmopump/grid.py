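"""Voxelisation of an orthorhombic box and membrane/solvent bin labelling.

A pumping cycle starts by tiling the simulation box with a rectangular
grid of bins (default edge ~1.3 nm, a good compromise for both
coarse-grained and atomistic systems). Bins that contain at least one
membrane particle are labelled 1 (membrane); every other bin is 0
(solvent). Particles that are neither membrane nor solvent (ions,
polymers, soluble proteins) never influence the labels but are tracked
as "solute" bin contents so that relocation can avoid their hydration
shells.

Bin counts are chosen per axis as ``n = max(1, round(l / target_edge))``
with the actual edge ``l / n``, so the bins tile the box exactly and the
system dimensions are conserved.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .errors import ConfigurationError, InputError, ParameterError

#: label value for a bin occupied by >=1 membrane particle
MEMBRANE = 1
#: label value for a solvent (unoccupied-by-membrane) bin
SOLVENT = 0
#: sentinel for bins already consumed by the clustering pass
VISITED = -1


class BoxVec(NamedTuple):
    """Orthorhombic box edge lengths in nm."""

    lx: float
    ly: float
    lz: float

    def validate(self) -> "BoxVec":
        if not all(np.isfinite(self)) or min(self) <= 0:
            raise ParameterError(f"box edges must be positive and finite, got {tuple(self)}")
        return self

    @property
    def volume(self) -> float:
        return self.lx * self.ly * self.lz

    def as_array(self) -> np.ndarray:
        return np.asarray(self, dtype=float)


@dataclass(frozen=True)
class GridSpec:
    """A rectangular grid of ``nx * ny * nz`` bins exactly tiling ``box``."""

    nx: int
    ny: int
    nz: int
    ex: float
    ey: float
    ez: float
    box: BoxVec

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.nx, self.ny, self.nz)

    @property
    def n_bins(self) -> int:
        return self.nx * self.ny * self.nz

    @property
    def edges(self) -> np.ndarray:
        return np.array([self.ex, self.ey, self.ez])

    @property
    def bin_volume(self) -> float:
        """Volume of a single bin, nm^3."""
        return self.ex * self.ey * self.ez

    def flatten(self, ijk: np.ndarray) -> np.ndarray:
        """C-order flat index of integer bin triples (..., 3)."""
        ijk = np.asarray(ijk)
        return (ijk[..., 0] * self.ny + ijk[..., 1]) * self.nz + ijk[..., 2]

    def unflatten(self, flat: np.ndarray) -> np.ndarray:
        flat = np.asarray(flat)
        i, rem = np.divmod(flat, self.ny * self.nz)
        j, k = np.divmod(rem, self.nz)
        return np.stack([i, j, k], axis=-1)

    def bin_lower_corner(self, ijk) -> np.ndarray:
        """Cartesian coordinate (nm) of the lower corner of bin ``ijk``."""
        return np.asarray(ijk, dtype=float) * self.edges

    def bin_center(self, ijk) -> np.ndarray:
        return (np.asarray(ijk, dtype=float) + 0.5) * self.edges


@dataclass(frozen=True)
class BinLabels:
    """Membrane/solvent occupancy field over a grid.

    ``labels[i, j, k]`` is 1 for a membrane bin, 0 for a solvent bin
    (-1 is reserved as the "visited" sentinel during clustering).
    """

    labels: np.ndarray
    grid: GridSpec

    def __post_init__(self):
        if self.labels.shape != self.grid.shape:
            raise InputError(
                f"label field shape {self.labels.shape} != grid shape {self.grid.shape}"
            )

    @property
    def n_membrane(self) -> int:
        return int(np.count_nonzero(self.labels == MEMBRANE))

    @property
    def n_solvent(self) -> int:
        return int(np.count_nonzero(self.labels == SOLVENT))


def make_grid(box: BoxVec, target_edge: float = 1.3) -> GridSpec:
    """Tile ``box`` with bins of edge as close to ``target_edge`` as possible.

    Per axis ``n = max(1, round(l / target_edge))`` and the actual edge is
    ``l / n``, so ``n * edge`` reproduces the box length exactly.

    Parameters
    ----------
    box : BoxVec
        Orthorhombic box edge lengths, nm.
    target_edge : float
        Requested bin edge in nm (default 1.3). Must be positive and no
        larger than the smallest box edge.
    """
    box = BoxVec(*box).validate()
    if not np.isfinite(target_edge) or target_edge <= 0:
        raise ParameterError(f"target_edge must be positive, got {target_edge}")
    if target_edge > min(box):
        raise ParameterError(
            f"target_edge {target_edge} exceeds smallest box edge {min(box)}"
        )
    n = [max(1, round(l / target_edge)) for l in box]
    ex, ey, ez = (l / ni for l, ni in zip(box, n))
    return GridSpec(n[0], n[1], n[2], ex, ey, ez, box)


def bin_index(positions: np.ndarray, grid: GridSpec) -> np.ndarray:
    """Map positions (nm) to integer bin triples, wrapping into the box.

    Accepts a single (3,) position or an (N, 3) array. Coordinates may lie
    outside ``[0, l)`` (MD engines emit unwrapped trajectories); they are
    wrapped periodically before binning. The result is guaranteed to lie in
    ``[0, n-1]`` per axis.
    """
    pos = np.asarray(positions, dtype=float)
    single = pos.ndim == 1
    pos = np.atleast_2d(pos)
    if pos.shape[-1] != 3:
        raise InputError(f"positions must have 3 coordinates, got shape {pos.shape}")
    if not np.all(np.isfinite(pos)):
        raise InputError("non-finite coordinate in positions")
    l = grid.box.as_array()
    wrapped = pos - np.floor(pos / l) * l
    idx = np.floor(wrapped / grid.edges).astype(np.int64)
    # guard against wrapped == l from floating round-off
    np.clip(idx, 0, np.array(grid.shape) - 1, out=idx)
    return idx[0] if single else idx


def label_bins(system, grid: GridSpec) -> BinLabels:
    """Label every bin that holds >=1 membrane particle with 1, rest 0.

    Only the ``membrane`` index group matters: ions, polymers and soluble
    proteins are omitted, so the label field reflects membrane occupancy
    alone. Everything residing *in* the membrane (cholesterol, embedded
    proteins) should therefore be part of the membrane group, or the bin
    structure may come out non-contiguous.
    """
    membrane = system.groups.get("membrane")
    if membrane is None or len(membrane) == 0:
        raise ConfigurationError(
            "system has no (non-empty) 'membrane' index group; all structures "
            "residing in the membrane should be in the same index group as the lipids"
        )
    labels = np.zeros(grid.shape, dtype=np.int8)
    idx = bin_index(system.positions[membrane], grid)
    labels[idx[:, 0], idx[:, 1], idx[:, 2]] = MEMBRANE
    return BinLabels(labels, grid)


@dataclass(frozen=True)
class BinContents:
    """Per-bin occupancy of solvent molecules and solute particles.

    Solvent molecules are assigned to exactly one bin each, by the position
    of their reference site (the molecule's first particle; for monatomic
    CG water that is the particle itself). Every particle that is in
    neither the membrane nor the solvent group counts as solute.
    """

    grid: GridSpec
    solvent_mol_ids: np.ndarray      # (S,) global molecule ids
    solvent_flat_bins: np.ndarray    # (S,) flat bin per solvent molecule
    solute_particle_ids: np.ndarray  # (Q,) global particle ids
    solute_flat_bins: np.ndarray     # (Q,)

    @property
    def solvent_count(self) -> np.ndarray:
        """Number of solvent molecules per flat bin."""
        return np.bincount(self.solvent_flat_bins, minlength=self.grid.n_bins)

    @property
    def solute_count(self) -> np.ndarray:
        """Number of solute particles per flat bin."""
        return np.bincount(self.solute_flat_bins, minlength=self.grid.n_bins)

    def solvent_in(self, ijk) -> np.ndarray:
        """Solvent molecule ids residing in bin ``ijk``."""
        flat = self.grid.flatten(np.asarray(ijk))
        return self.solvent_mol_ids[self.solvent_flat_bins == flat]

    def solute_in(self, ijk) -> np.ndarray:
        """Solute particle ids residing in bin ``ijk``."""
        flat = self.grid.flatten(np.asarray(ijk))
        return self.solute_particle_ids[self.solute_flat_bins == flat]

    @property
    def n_solvent(self) -> int:
        return len(self.solvent_mol_ids)


def bin_contents(system, grid: GridSpec) -> BinContents:
    """Assign solvent molecules (by reference site) and solute particles to bins."""
    solvent = np.asarray(
        system.groups.get("solvent", np.empty(0, dtype=np.int64)), dtype=np.int64
    )
    in_solvent = np.zeros(system.n_particles, dtype=bool)
    in_solvent[solvent] = True
    starts = np.asarray(system.molecules, dtype=np.int64)[:, 0]
    # a molecule is solvent iff its reference site is in the solvent group
    mol_ids = np.flatnonzero(in_solvent[starts])
    ref_sites = starts[mol_ids]
    if len(ref_sites):
        solvent_bins = grid.flatten(bin_index(system.positions[ref_sites], grid))
    else:
        solvent_bins = np.empty(0, dtype=np.int64)

    membrane = system.groups.get("membrane", np.empty(0, dtype=np.int64))
    mask = np.ones(system.n_particles, dtype=bool)
    mask[np.asarray(membrane, dtype=np.int64)] = False
    mask[solvent] = False
    solute_ids = np.flatnonzero(mask)
    if len(solute_ids):
        solute_bins = grid.flatten(bin_index(system.positions[solute_ids], grid))
    else:
        solute_bins = np.empty(0, dtype=np.int64)
    return BinContents(grid, mol_ids, solvent_bins, solute_ids, solute_bins)
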