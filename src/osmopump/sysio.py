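"""File I/O (GRO / NDX / TOP) and synthetic fixture systems.

The on-disk formats follow the GROMACS conventions: fixed-column GRO
coordinates in nm (positions printed at 3 decimals, velocities at 4),
bracketed NDX group headers with 1-based particle indices, and a TOP
``[ molecules ]`` section listing (name, count) pairs. Internally
everything is 0-based; the conversion happens only at the I/O boundary.

The fixture generators build fully synthetic vesicle / pored-vesicle /
double-bilayer systems (membrane sites on Fibonacci-sphere or planar
lattices, solvent on a jittered lattice) so the whole pumping pipeline is
testable without an MD engine or any external structure builder.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, ConsistencyError, FormatError, ParameterError
from .grid import BoxVec


@dataclass
class ParticleSystem:
    """A particle configuration plus the grouping metadata the protocol needs.

    Attributes
    ----------
    positions : (N, 3) float array, nm
    velocities : (N, 3) float array, nm/ps, or None if the source had none
    names : (N,) atom names
    resnames : (N,) residue names
    resids : (N,) residue ids (used to derive the molecule partition)
    molecules : (M, 2) int array of [start, stop) particle-index ranges
    box : BoxVec, nm
    groups : named index sets; ``membrane`` and ``solvent`` are required by
        the pumping pipeline and must not overlap
    meta : free-form bookkeeping written by the fixture generators
    """

    positions: np.ndarray
    velocities: np.ndarray | None
    names: np.ndarray
    resnames: np.ndarray
    resids: np.ndarray
    molecules: np.ndarray
    box: BoxVec
    groups: dict[str, np.ndarray] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    @property
    def n_particles(self) -> int:
        return len(self.positions)

    @property
    def n_molecules(self) -> int:
        return len(self.molecules)

    def molecule_of(self) -> np.ndarray:
        """(N,) molecule index of every particle."""
        out = np.empty(self.n_particles, dtype=np.int64)
        for m, (a, b) in enumerate(self.molecules):
            out[a:b] = m
        return out

    def copy(self) -> "ParticleSystem":
        return ParticleSystem(
            positions=self.positions.copy(),
            velocities=None if self.velocities is None else self.velocities.copy(),
            names=self.names.copy(),
            resnames=self.resnames.copy(),
            resids=self.resids.copy(),
            molecules=self.molecules.copy(),
            box=BoxVec(*self.box),
            groups={k: v.copy() for k, v in self.groups.items()},
            meta=dict(self.meta),
        )

    def validate_groups(self) -> None:
        mem = set(self.groups.get("membrane", ()))
        sol = set(self.groups.get("solvent", ()))
        overlap = mem & sol
        if overlap:
            raise ConfigurationError(
                f"membrane and solvent groups overlap ({len(overlap)} particles)"
            )
        for name, idx in self.groups.items():
            idx = np.asarray(idx)
            if len(idx) and (idx.min() < 0 or idx.max() >= self.n_particles):
                raise ConfigurationError(f"group '{name}' references invalid indices")


def molecules_from_resids(resids: np.ndarray) -> np.ndarray:
    """Derive the molecule partition: a run of equal consecutive resids = one molecule."""
    resids = np.asarray(resids)
    if len(resids) == 0:
        return np.empty((0, 2), dtype=np.int64)
    change = np.flatnonzero(resids[1:] != resids[:-1]) + 1
    starts = np.concatenate([[0], change])
    stops = np.concatenate([change, [len(resids)]])
    return np.stack([starts, stops], axis=1).astype(np.int64)


# ---------------------------------------------------------------------------
# GRO
# ---------------------------------------------------------------------------

def read_gro(path) -> ParticleSystem:
    """Read a fixed-column GRO file (orthorhombic box, nm units)."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) < 3:
        raise FormatError(f"{path}: truncated GRO file")
    try:
        natoms = int(lines[1].strip())
    except ValueError as e:
        raise FormatError(f"{path}: malformed atom-count line {lines[1]!r}") from e
    if len(lines) < natoms + 3:
        raise FormatError(f"{path}: expected {natoms} atom lines, file too short")

    box_fields = lines[natoms + 2].split()
    if len(box_fields) == 3:
        diag = [float(x) for x in box_fields]
    elif len(box_fields) == 9:
        vals = [float(x) for x in box_fields]
        if any(abs(v) > 1e-9 for v in vals[3:]):
            raise FormatError(f"{path}: triclinic box with off-diagonal terms unsupported")
        diag = vals[:3]
    else:
        raise FormatError(f"{path}: malformed box line {lines[natoms + 2]!r}")
    box = BoxVec(*diag).validate()

    resids = np.empty(natoms, dtype=np.int64)
    resnames = np.empty(natoms, dtype=object)
    names = np.empty(natoms, dtype=object)
    pos = np.empty((natoms, 3), dtype=float)
    first = lines[2]
    has_vel = len(first.rstrip("\n")) >= 68
    vel = np.zeros((natoms, 3), dtype=float) if has_vel else None
    for i in range(natoms):
        ln = lines[2 + i]
        try:
            resids[i] = int(ln[0:5])
            resnames[i] = ln[5:10].strip()
            names[i] = ln[10:15].strip()
            pos[i] = (float(ln[20:28]), float(ln[28:36]), float(ln[36:44]))
            if has_vel:
                vel[i] = (float(ln[44:52]), float(ln[52:60]), float(ln[60:68]))
        except (ValueError, IndexError) as e:
            raise FormatError(f"{path}: malformed atom line {i + 3}: {ln!r}") from e

    return ParticleSystem(
        positions=pos,
        velocities=vel,
        names=names.astype(str),
        resnames=resnames.astype(str),
        resids=resids,
        molecules=molecules_from_resids(resids),
        box=box,
    )


def write_gro(system: ParticleSystem, path, title: str = "osmopump system") -> None:
    """Write a GRO file (positions %8.3f; velocities %8.4f when present)."""
    n = system.n_particles
    has_vel = system.velocities is not None
    with open(path, "w") as fh:
        fh.write(f"{title}\n{n:5d}\n")
        for i in range(n):
            resid = int(system.resids[i]) % 100000
            atomid = (i + 1) % 100000
            x, y, z = system.positions[i]
            line = (
                f"{resid:5d}{system.resnames[i]:<5.5s}{system.names[i]:>5.5s}"
                f"{atomid:5d}{x:8.3f}{y:8.3f}{z:8.3f}"
            )
            if has_vel:
                vx, vy, vz = system.velocities[i]
                line += f"{vx:8.4f}{vy:8.4f}{vz:8.4f}"
            fh.write(line + "\n")
        fh.write(f"{system.box.lx:10.5f}{system.box.ly:10.5f}{system.box.lz:10.5f}\n")


# ---------------------------------------------------------------------------
# NDX
# ---------------------------------------------------------------------------

def read_ndx(path, require: tuple[str, ...] = ("membrane", "solvent")) -> dict[str, np.ndarray]:
    """Read a GROMACS index file into 0-based named groups.

    By default both a ``membrane`` and a ``solvent`` group must be present
    (the pumping pipeline needs them); pass ``require=()`` to relax.
    """
    groups: dict[str, list[int]] = {}
    current: list[int] | None = None
    with open(path) as fh:
        for ln in fh:
            ln = ln.split(";")[0].strip()
            if not ln:
                continue
            if ln.startswith("[") and ln.endswith("]"):
                name = ln[1:-1].strip()
                current = groups.setdefault(name, [])
            else:
                if current is None:
                    raise FormatError(f"{path}: indices before any [ group ] header")
                try:
                    current.extend(int(tok) - 1 for tok in ln.split())
                except ValueError as e:
                    raise FormatError(f"{path}: non-integer index in line {ln!r}") from e
    out = {k: np.asarray(v, dtype=np.int64) for k, v in groups.items()}
    for name in require:
        if name not in out or len(out[name]) == 0:
            raise ConfigurationError(
                f"{path}: index file must discern a non-empty '{name}' group; "
                "everything residing in the membrane (proteins, sterols) should "
                "be in the same index group as the lipids"
            )
    if "membrane" in out and "solvent" in out:
        if np.intersect1d(out["membrane"], out["solvent"]).size:
            raise ConfigurationError(f"{path}: membrane and solvent groups overlap")
    return out


def write_ndx(groups: dict[str, np.ndarray], path) -> None:
    """Write named 0-based index groups as a 1-based NDX file."""
    with open(path, "w") as fh:
        for name, idx in groups.items():
            fh.write(f"[ {name} ]\n")
            idx = np.asarray(idx, dtype=np.int64) + 1
            for start in range(0, len(idx), 15):
                fh.write(" ".join(str(i) for i in idx[start : start + 15]) + "\n")


# ---------------------------------------------------------------------------
# TOP
# ---------------------------------------------------------------------------

@dataclass
class TopologyDoc:
    """A topology file reduced to its molecule counts plus passthrough text.

    Only the ``[ molecules ]`` section is interpreted; everything before it
    is kept verbatim so a read/modify/write cycle does not destroy
    force-field includes or comments.
    """

    molecules: list[tuple[str, int]]
    pre_block: str = ""

    def total_count(self) -> int:
        return sum(c for _, c in self.molecules)


def read_top(path) -> TopologyDoc:
    with open(path) as fh:
        text = fh.read()
    lines = text.splitlines(keepends=True)
    mol_header = None
    for i, ln in enumerate(lines):
        stripped = ln.split(";")[0].strip().lower().replace(" ", "")
        if stripped == "[molecules]":
            mol_header = i
            break
    if mol_header is None:
        raise FormatError(f"{path}: no [ molecules ] section")
    molecules: list[tuple[str, int]] = []
    for ln in lines[mol_header + 1 :]:
        stripped = ln.split(";")[0].strip()
        if not stripped:
            continue
        if stripped.startswith("["):
            raise FormatError(f"{path}: unexpected section after [ molecules ]")
        parts = stripped.split()
        if len(parts) != 2:
            raise FormatError(f"{path}: malformed molecules line {ln!r}")
        try:
            count = int(parts[1])
        except ValueError as e:
            raise FormatError(f"{path}: non-integer molecule count in {ln!r}") from e
        if count < 0:
            raise FormatError(f"{path}: negative molecule count in {ln!r}")
        molecules.append((parts[0], count))
    return TopologyDoc(molecules=molecules, pre_block="".join(lines[:mol_header]))


def write_top(doc: TopologyDoc, path) -> None:
    with open(path, "w") as fh:
        fh.write(doc.pre_block)
        fh.write("[ molecules ]\n")
        for name, count in doc.molecules:
            fh.write(f"{name} {count}\n")


def check_top_consistency(doc: TopologyDoc, system: ParticleSystem) -> None:
    """Verify the TOP molecule counts against the GRO molecule partition.

    Molecules are matched by the residue name of their first particle,
    run-length compressed in file order — the ordering GROMACS requires.
    Relocation conserves counts, so this holds across an entire run.
    """
    names = [str(system.resnames[a]) for a, _ in system.molecules]
    runs: list[tuple[str, int]] = []
    for nm in names:
        if runs and runs[-1][0] == nm:
            runs[-1] = (nm, runs[-1][1] + 1)
        else:
            runs.append((nm, 1))
    if runs != list(doc.molecules):
        raise ConsistencyError(
            f"topology molecule counts {doc.molecules} do not match the "
            f"configuration's molecule runs {runs}"
        )


def default_topology(system: ParticleSystem) -> TopologyDoc:
    """Build a TopologyDoc whose counts match ``system`` (fixture helper)."""
    names = [str(system.resnames[a]) for a, _ in system.molecules]
    runs: list[tuple[str, int]] = []
    for nm in names:
        if runs and runs[-1][0] == nm:
            runs[-1] = (nm, runs[-1][1] + 1)
        else:
            runs.append((nm, 1))
    return TopologyDoc(molecules=runs, pre_block="; synthetic osmopump fixture\n")


# ---------------------------------------------------------------------------
# Fixture generators
# ---------------------------------------------------------------------------

def fibonacci_sphere(n: int) -> np.ndarray:
    """n near-uniform points on the unit sphere (golden-angle spiral)."""
    if n < 1:
        raise ParameterError("need at least one point")
    i = np.arange(n, dtype=float)
    golden = math.pi * (3.0 - math.sqrt(5.0))
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    theta = golden * i
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def _solvent_lattice(box: BoxVec, density: float, rng: np.random.Generator) -> np.ndarray:
    """Jittered cubic lattice filling the box at the given number density (nm^-3)."""
    if density <= 0:
        raise ParameterError(f"solvent density must be positive, got {density}")
    a = density ** (-1.0 / 3.0)
    counts = [max(1, int(round(l / a))) for l in box]
    spacing = [l / c for l, c in zip(box, counts)]
    gx, gy, gz = np.meshgrid(
        *[(np.arange(c) + 0.5) * s for c, s in zip(counts, spacing)], indexing="ij"
    )
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    jitter = rng.uniform(-0.2, 0.2, size=pts.shape) * np.array(spacing)
    return pts + jitter


def _assemble(
    box: BoxVec,
    membrane_pos: np.ndarray,
    membrane_names: np.ndarray,
    solvent_pos: np.ndarray,
    ion_pos: np.ndarray,
    membrane_resname: str = "LIP",
) -> ParticleSystem:
    """Stack membrane / water / ion blocks into a ParticleSystem.

    Every site is its own single-particle molecule (CG-style beads), which
    keeps the fixtures simple while exercising the same bookkeeping paths
    as multi-site molecules.
    """
    n_mem, n_sol, n_ion = len(membrane_pos), len(solvent_pos), len(ion_pos)
    n = n_mem + n_sol + n_ion
    pos = np.vstack([p for p in (membrane_pos, solvent_pos, ion_pos) if len(p)])
    names = np.concatenate(
        [
            membrane_names,
            np.full(n_sol, "W", dtype=object),
            np.array((["NA", "CL"] * ((n_ion + 1) // 2))[:n_ion], dtype=object),
        ]
    ).astype(str)
    resnames = np.concatenate(
        [
            np.full(n_mem, membrane_resname, dtype=object),
            np.full(n_sol, "W", dtype=object),
            names[n_mem + n_sol :].astype(object),
        ]
    ).astype(str)
    resids = np.arange(1, n + 1, dtype=np.int64)
    groups = {
        "membrane": np.arange(n_mem, dtype=np.int64),
        "solvent": np.arange(n_mem, n_mem + n_sol, dtype=np.int64),
    }
    if n_ion:
        groups["ions"] = np.arange(n_mem + n_sol, n, dtype=np.int64)
    sys_ = ParticleSystem(
        positions=pos,
        velocities=np.zeros((n, 3)),
        names=names,
        resnames=resnames,
        resids=resids,
        molecules=molecules_from_resids(resids),
        box=box,
        groups=groups,
    )
    sys_.validate_groups()
    return sys_


def _shell_sites(
    center: np.ndarray,
    r_inner: float,
    r_outer: float,
    site_spacing: float,
    max_radial_step: float = 0.55,
) -> tuple[np.ndarray, np.ndarray]:
    """Concentric Fibonacci shells spanning [r_inner, r_outer].

    The innermost and outermost shells carry the leaflet linker sites
    (name GL1); filler shells in between (name C1A) keep the membrane
    voxel-contiguous at the default 1.3 nm bin edge.
    """
    n_shells = max(2, int(math.ceil((r_outer - r_inner) / max_radial_step)) + 1)
    radii = np.linspace(r_inner, r_outer, n_shells)
    pos_blocks, name_blocks = [], []
    for s, r in enumerate(radii):
        n_sites = max(8, int(math.ceil(4.0 * math.pi * r * r / site_spacing**2)))
        pts = center + r * fibonacci_sphere(n_sites)
        nm = "GL1" if s in (0, n_shells - 1) else "C1A"
        pos_blocks.append(pts)
        name_blocks.append(np.full(n_sites, nm, dtype=object))
    return np.vstack(pos_blocks), np.concatenate(name_blocks)


def make_vesicle(
    r_mid: float = 6.0,
    thickness: float = 2.0,
    box: BoxVec = BoxVec(20.0, 20.0, 20.0),
    site_spacing: float = 0.5,
    solvent_density: float = 8.3,
    ion_pairs: int = 0,
    seed: int = 0,
    solvent_buffer: float = 0.3,
) -> ParticleSystem:
    """Synthetic spherical vesicle: two linker shells at ``r_mid +- thickness/2``
    plus filler shells, solvent inside and outside on a jittered lattice.

    Defaults emulate a small Martini-scale vesicle: 0.5 nm site spacing
    (dense enough that every bin the membrane crosses is a membrane bin at
    1.3 nm edges) and 8.3 solvent beads/nm^3 (bulk CG water, four waters
    per bead). Optional Na/Cl ion pairs go in the exterior. Deterministic
    under ``seed``.
    """
    box = BoxVec(*box).validate()
    r_out = r_mid + thickness / 2.0
    r_in = r_mid - thickness / 2.0
    if r_in <= 0:
        raise ParameterError("thickness exceeds vesicle diameter")
    if r_out + solvent_buffer >= min(box) / 2.0:
        raise ParameterError(
            f"vesicle (outer radius {r_out}) does not fit in half the box {min(box) / 2}"
        )
    rng = np.random.default_rng(seed)
    center = box.as_array() / 2.0
    mem_pos, mem_names = _shell_sites(center, r_in, r_out, site_spacing)

    lattice = _solvent_lattice(box, solvent_density, rng)
    d = np.linalg.norm(lattice - center, axis=1)
    interior = lattice[d < r_in - solvent_buffer]
    exterior = lattice[d > r_out + solvent_buffer]
    solvent_pos = np.vstack([interior, exterior])

    n_ion = 2 * ion_pairs
    ion_pos = np.empty((0, 3))
    if n_ion:
        ions = []
        while len(ions) < n_ion:
            cand = rng.uniform(0.0, 1.0, size=(n_ion * 4, 3)) * box.as_array()
            dd = np.linalg.norm(cand - center, axis=1)
            ions.extend(cand[dd > r_out + solvent_buffer][: n_ion - len(ions)])
        ion_pos = np.asarray(ions)

    sys_ = _assemble(box, mem_pos, mem_names, solvent_pos, ion_pos)
    sys_.meta.update(
        kind="vesicle",
        r_mid=r_mid,
        thickness=thickness,
        interior_solvent=len(interior),
        exterior_solvent=len(exterior),
        seed=seed,
    )
    return sys_


def make_pored_vesicle(
    pore_radius: float = 3.0,
    bin_edge: float = 1.3,
    **vesicle_kwargs,
) -> ParticleSystem:
    """Vesicle with a spherical-cap hole around the +z pole.

    ``pore_radius`` is the arc radius of the cap on the mid-surface and
    must be at least two bin edges so the pore is guaranteed to open a
    voxel channel between the compartments.
    """
    if pore_radius < 2.0 * bin_edge:
        raise ParameterError(
            f"pore radius {pore_radius} nm below the 2-bin-edge minimum "
            f"({2.0 * bin_edge} nm): voxel connectivity through the pore "
            "cannot be guaranteed"
        )
    sys_ = make_vesicle(**vesicle_kwargs)
    r_mid = sys_.meta["r_mid"]
    center = sys_.box.as_array() / 2.0
    mem = sys_.groups["membrane"]
    rel = sys_.positions[mem] - center
    rad = np.linalg.norm(rel, axis=1)
    polar = np.arccos(np.clip(rel[:, 2] / np.maximum(rad, 1e-12), -1.0, 1.0))
    theta = pore_radius / r_mid
    keep_mask = polar >= theta  # drop sites inside the cap
    keep_mem = mem[keep_mask]

    # rebuild with the reduced membrane
    mem_pos = sys_.positions[keep_mem]
    mem_names = sys_.names[keep_mem].astype(object)
    sol = sys_.groups["solvent"]
    ion = sys_.groups.get("ions", np.empty(0, dtype=np.int64))
    out = _assemble(sys_.box, mem_pos, mem_names, sys_.positions[sol], sys_.positions[ion])
    out.meta.update(dict(sys_.meta), kind="pored_vesicle", pore_radius=pore_radius)
    return out


def make_double_bilayer(
    gap: float = 8.0,
    box: BoxVec = BoxVec(10.0, 10.0, 25.0),
    slab_thickness: float = 2.0,
    site_spacing: float = 0.5,
    solvent_density: float = 8.3,
    seed: int = 0,
    solvent_buffer: float = 0.3,
) -> ParticleSystem:
    """Two planar membrane slabs spanning x-y with a central solvent gap.

    Mirrors the classic double-bilayer setup (default 10 x 10 x 25 nm box
    with an 8 nm gap): the central compartment between the slabs is the
    inner compartment, the outer solvent connects to itself through the
    periodic z boundary.
    """
    box = BoxVec(*box).validate()
    if 2 * slab_thickness + gap >= box.lz:
        raise ParameterError(
            f"two slabs of {slab_thickness} nm plus a {gap} nm gap do not fit lz={box.lz}"
        )
    rng = np.random.default_rng(seed)
    zc = box.lz / 2.0
    slab_centers = (zc - (gap + slab_thickness) / 2.0, zc + (gap + slab_thickness) / 2.0)

    nx = max(2, int(round(box.lx / site_spacing)))
    ny = max(2, int(round(box.ly / site_spacing)))
    xs = (np.arange(nx) + 0.5) * (box.lx / nx)
    ys = (np.arange(ny) + 0.5) * (box.ly / ny)
    n_layers = max(2, int(math.ceil(slab_thickness / 0.55)) + 1)
    pos_blocks, name_blocks = [], []
    for zc_slab in slab_centers:
        layers = np.linspace(zc_slab - slab_thickness / 2.0, zc_slab + slab_thickness / 2.0, n_layers)
        for li, z in enumerate(layers):
            gx, gy = np.meshgrid(xs, ys, indexing="ij")
            pts = np.column_stack([gx.ravel(), gy.ravel(), np.full(gx.size, z)])
            nm = "GL1" if li in (0, n_layers - 1) else "C1A"
            pos_blocks.append(pts)
            name_blocks.append(np.full(len(pts), nm, dtype=object))
    mem_pos = np.vstack(pos_blocks)
    mem_names = np.concatenate(name_blocks)

    lattice = _solvent_lattice(box, solvent_density, rng)
    z = lattice[:, 2]
    lo = (slab_centers[0] - slab_thickness / 2.0, slab_centers[0] + slab_thickness / 2.0)
    hi = (slab_centers[1] - slab_thickness / 2.0, slab_centers[1] + slab_thickness / 2.0)
    central = (z > lo[1] + solvent_buffer) & (z < hi[0] - solvent_buffer)
    outer = (z < lo[0] - solvent_buffer) | (z > hi[1] + solvent_buffer)
    interior = lattice[central]
    exterior = lattice[outer]
    solvent_pos = np.vstack([interior, exterior])

    sys_ = _assemble(box, mem_pos, mem_names, solvent_pos, np.empty((0, 3)))
    sys_.meta.update(
        kind="double_bilayer",
        gap=gap,
        slab_thickness=slab_thickness,
        interior_solvent=len(interior),
        exterior_solvent=len(exterior),
        seed=seed,
    )
    return sys_
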