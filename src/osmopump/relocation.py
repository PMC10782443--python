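"""Solvent selection and low-overlap relocation between compartments.

One pumping step moves ``k`` solvent molecules from the source to the
target compartment. Bins are drawn at random from the source compartment
— preferring bins that contain nothing but solvent, so hydration shells
of solutes stay untouched — and a single molecule per bin is taken, which
disperses the removal over the whole compartment. Each molecule is
re-inserted at the best of ``n_trials`` random trial points inside a
target bin (shrunk by a safety margin on every face, default 0.3 nm, to
avoid particles in neighbouring bins), "best" meaning the largest
minimum-image distance to every particle in the bin and its 26
neighbours. Molecules are translated rigidly and keep their velocities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .compartments import MEMBRANE_SENTINEL, CompartmentMap
from .errors import InputError, ParameterError, SolventExhaustedError, StateError
from .grid import BinContents, GridSpec, bin_index
from .sysio import ParticleSystem


@dataclass(frozen=True)
class Move:
    """One planned relocation: molecule, where from, where to."""

    molecule: int
    source_bin: tuple[int, int, int]
    target_bin: tuple[int, int, int]
    point: np.ndarray        # insertion point, nm
    clearance: float         # min-image distance to nearest neighbour, nm


@dataclass
class RelocationPlan:
    """The set of moves for one pumping step.

    Source bins are unique (one molecule per bin) and so are molecule
    ids. ``shortfall`` is True when fewer eligible bins existed than
    requested moves.
    """

    moves: list[Move] = field(default_factory=list)
    shortfall: bool = False

    def __len__(self) -> int:
        return len(self.moves)

    def validate(self) -> None:
        mols = [m.molecule for m in self.moves]
        if len(set(mols)) != len(mols):
            raise InputError("duplicate molecule ids in relocation plan")
        srcs = [m.source_bin for m in self.moves]
        if len(set(srcs)) != len(srcs):
            raise InputError("duplicate source bins in relocation plan")


def select_source_bins(
    cmap: CompartmentMap,
    contents: BinContents,
    n: int,
    rng: np.random.Generator,
    source_id: int,
) -> tuple[list[tuple[int, int, int]], bool]:
    """Draw up to ``n`` distinct source bins from compartment ``source_id``.

    Bins whose contents are solvent-only are preferred; bins that also
    hold solute particles are used only once the solvent-only pool is
    exhausted. Returns ``(bins, shortfall)`` where shortfall flags that
    fewer than ``n`` bins held any solvent at all.
    """
    if n < 1:
        raise ParameterError(f"need n >= 1 source bins, got {n}")
    grid = contents.grid
    cluster_flat = cmap.cluster_id.ravel()
    solvent_count = contents.solvent_count
    solute_count = contents.solute_count
    in_source = cluster_flat == source_id
    has_solvent = solvent_count > 0
    eligible = np.flatnonzero(in_source & has_solvent)
    if eligible.size == 0:
        raise SolventExhaustedError(
            f"no solvent molecules available for pumping in compartment {source_id}"
        )
    pure = eligible[solute_count[eligible] == 0]
    mixed = eligible[solute_count[eligible] > 0]

    chosen: list[int] = []
    take_pure = min(n, pure.size)
    if take_pure:
        chosen.extend(rng.choice(pure, size=take_pure, replace=False).tolist())
    remaining = n - len(chosen)
    if remaining > 0 and mixed.size:
        take_mixed = min(remaining, mixed.size)
        chosen.extend(rng.choice(mixed, size=take_mixed, replace=False).tolist())
    shortfall = len(chosen) < n
    ijk = grid.unflatten(np.asarray(chosen, dtype=np.int64))
    return [tuple(int(v) for v in row) for row in ijk], shortfall


def find_molecules_in_bins(
    system: ParticleSystem,
    grid: GridSpec,
    bins: list[tuple[int, int, int]],
    rng: np.random.Generator,
    contents: BinContents | None = None,
) -> list[int]:
    """Pick one resident solvent molecule, uniformly, from each bin."""
    from .grid import bin_contents as _bin_contents

    if contents is None:
        contents = _bin_contents(system, grid)
    out: list[int] = []
    for b in bins:
        residents = contents.solvent_in(b)
        if residents.size == 0:
            raise StateError(f"bin {b} holds no solvent molecule (selection contract violated)")
        out.append(int(rng.choice(residents)))
    return out


def choose_target_bin(
    cmap: CompartmentMap,
    contents: BinContents,
    rng: np.random.Generator,
    target_id: int,
) -> tuple[int, int, int]:
    """A random solute-free bin of the target compartment.

    When every target bin holds solute, fall back to a uniform draw among
    the bins achieving the minimum solute count.
    """
    cluster_flat = cmap.cluster_id.ravel()
    candidates = np.flatnonzero(cluster_flat == target_id)
    if candidates.size == 0:
        raise StateError(f"target compartment {target_id} has zero bins")
    solute = contents.solute_count[candidates]
    free = candidates[solute == 0]
    pool = free if free.size else candidates[solute == solute.min()]
    flat = int(rng.choice(pool))
    return tuple(int(v) for v in contents.grid.unflatten(flat))


def min_image_distances(points: np.ndarray, others: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Minimum distance of each point to the set ``others`` under minimum image.

    Returns +inf per point when ``others`` is empty.
    """
    points = np.atleast_2d(points)
    if len(others) == 0:
        return np.full(len(points), np.inf)
    diff = points[:, None, :] - others[None, :, :]
    diff -= np.round(diff / box) * box
    return np.sqrt((diff**2).sum(axis=2)).min(axis=1)


def insertion_point(
    grid: GridSpec,
    target_bin: tuple[int, int, int],
    nearby_positions: np.ndarray,
    margin: float = 0.3,
    n_trials: int = 100,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, float]:
    """Best-of-``n_trials`` trial insertion inside the margin-shrunk bin.

    Candidates are uniform in the bin shrunk by ``margin`` on every face;
    the returned point maximises the minimum-image distance to
    ``nearby_positions`` (all particles of the bin and its 26 neighbours).
    The achieved clearance is returned alongside; with no nearby
    particles it is +inf. Poor clearance is reported, never raised — the
    controller's recovery path owns that decision.
    """
    if rng is None:
        rng = np.random.default_rng()
    if n_trials < 1:
        raise ParameterError(f"n_trials must be >= 1, got {n_trials}")
    if margin < 0 or margin >= min(grid.ex, grid.ey, grid.ez) / 2.0:
        raise ParameterError(
            f"margin {margin} must be in [0, half the smallest bin edge "
            f"{min(grid.ex, grid.ey, grid.ez) / 2.0})"
        )
    lo = grid.bin_lower_corner(target_bin) + margin
    hi = grid.bin_lower_corner(target_bin) + grid.edges - margin
    cand = rng.uniform(lo, hi, size=(n_trials, 3))
    d = min_image_distances(cand, np.asarray(nearby_positions), grid.box.as_array())
    best = int(np.argmax(d))
    return cand[best], float(d[best])


def gather_nearby(
    system: ParticleSystem,
    grid: GridSpec,
    target_bin: tuple[int, int, int],
    particle_bins: np.ndarray | None = None,
    exclude_particles: np.ndarray | None = None,
) -> np.ndarray:
    """Positions of every particle in ``target_bin`` and its 26 neighbours.

    ``particle_bins`` (flat bin per particle) can be passed to amortise
    the binning across many insertions within one cycle.
    """
    if particle_bins is None:
        particle_bins = grid.flatten(bin_index(system.positions, grid))
    ijk = np.asarray(target_bin)
    offs = np.array([(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)])
    neigh = (ijk + offs) % np.array(grid.shape)
    flat_neigh = np.unique(grid.flatten(neigh))
    mask = np.isin(particle_bins, flat_neigh)
    if exclude_particles is not None:
        mask[exclude_particles] = False
    return system.positions[mask]


def plan_relocation(
    system: ParticleSystem,
    grid: GridSpec,
    cmap: CompartmentMap,
    contents: BinContents,
    n: int,
    source_id: int,
    target_id: int,
    rng: np.random.Generator,
    margin: float = 0.3,
    n_trials: int = 100,
) -> RelocationPlan:
    """Assemble a full plan: source bins -> molecules -> target bins -> points."""
    bins, shortfall = select_source_bins(cmap, contents, n, rng, source_id)
    mols = find_molecules_in_bins(system, grid, bins, rng, contents=contents)
    particle_bins = grid.flatten(bin_index(system.positions, grid))
    moves: list[Move] = []
    for b, mol in zip(bins, mols):
        tbin = choose_target_bin(cmap, contents, rng, target_id)
        # exclude the molecule being moved from its own clearance check
        a, z = system.molecules[mol]
        nearby = gather_nearby(
            system, grid, tbin, particle_bins=particle_bins,
            exclude_particles=np.arange(a, z),
        )
        point, clearance = insertion_point(grid, tbin, nearby, margin, n_trials, rng)
        moves.append(Move(mol, b, tbin, point, clearance))
    plan = RelocationPlan(moves=moves, shortfall=shortfall)
    plan.validate()
    return plan


def apply_relocation(system: ParticleSystem, plan: RelocationPlan) -> ParticleSystem:
    """Execute a plan: rigid translation of each molecule to its insertion point.

    The molecule's reference site (first particle) lands exactly on the
    insertion point; intramolecular geometry and all velocities are
    untouched, and no particle is created or destroyed — an empty plan
    returns an identical copy.
    """
    solvent = set(int(i) for i in system.groups.get("solvent", ()))
    out = system.copy()
    for mv in plan.moves:
        a, z = system.molecules[mv.molecule]
        if int(a) not in solvent:
            raise StateError(f"molecule {mv.molecule} is no longer in the solvent group")
        shift = np.asarray(mv.point) - system.positions[a]
        out.positions[a:z] = system.positions[a:z] + shift
    return out
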