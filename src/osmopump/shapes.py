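"""Vesicle shape analysis: unwrapping, leaflet surfaces, shape descriptors.

Deformation pathways are tracked with a small set of dimensionless
descriptors computed after each pumping cycle:

* reduced volume  ``v = 6 sqrt(pi) V / A^(3/2)`` — 1 for a sphere, < 1
  for deflated shapes;
* reduced area difference ``da = (A_out - A_in) / (8 pi d R_A)`` with
  ``R_A = sqrt(A_mid / 4 pi)`` — the leaflet-area asymmetry normalised
  by membrane thickness ``d`` and the equivalent-sphere radius; 1 for a
  sphere;
* asphericity ``D = [(l1-l2)^2 + (l2-l3)^2 + (l3-l1)^2] / (2 (l1+l2+l3)^2)``
  from the gyration-tensor eigenvalues ``l1 >= l2 >= l3`` — 0 for a
  sphere, 1 for a thin rod;
* oblicity ``S = prod_i (l_i - lmean) / lmean^3`` — sign-resolved shape:
  negative for oblate (disk-like, bound -0.25), positive for prolate
  (rod-like, bound 2).

Every shape in the volume/area-difference plane is unique, so plotting
(v, da) per cycle gives the classic vesicle shape diagram. All four
formulas are centralised here, so adopting a different normalisation is
a one-line change.

Surfaces are built per leaflet from the lipid linker sites after the
membrane has been made whole across periodic boundaries; the default
surface backend is the convex hull (exact for convex point clouds), and
non-convex backends can be plugged in as callables.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

from .compartments import periodic_label
from .errors import GeometryError, InputError, ParameterError, ReconstructionError
from .grid import bin_index, make_grid
from .sysio import ParticleSystem


@dataclass(frozen=True)
class ShapeMetrics:
    """Per-frame shape record of a vesicle."""

    A_out: float
    A_in: float
    A_mid: float
    V: float
    v: float
    da: float
    asphericity: float
    oblicity: float
    R_out: float
    R_in: float
    thickness: float


# ---------------------------------------------------------------------------
# PBC unwrapping
# ---------------------------------------------------------------------------

def unwrap(system: ParticleSystem, group: np.ndarray, cutoff: float | None = None) -> np.ndarray:
    """Shift a group's coordinates by box vectors so it forms one whole object.

    The group is voxelised at ``cutoff`` (default 1.5 x 1.3 nm) and the
    occupied voxels are flood-filled across the periodic boundaries,
    accumulating an integer box-shift per voxel; particle coordinates are
    then moved by their voxel's shift and the centroid is placed in the
    primary box. Fails explicitly — rather than silently misassembling —
    when the group is split into disconnected pieces at the cutoff, or
    when it wraps all the way around the box (multiple PBC crossings).
    """
    group = np.asarray(group, dtype=np.int64)
    if len(group) == 0:
        raise InputError("cannot unwrap an empty group")
    if cutoff is None:
        cutoff = 1.5 * 1.3
    grid = make_grid(system.box, cutoff)
    box = system.box.as_array()
    pos = system.positions[group]
    wrapped = pos - np.floor(pos / box) * box
    ijk = bin_index(wrapped, grid)
    mask = np.zeros(grid.shape, dtype=bool)
    mask[ijk[:, 0], ijk[:, 1], ijk[:, 2]] = True
    labels, n = periodic_label(mask)
    if n != 1:
        raise ReconstructionError(
            f"group splits into {n} disconnected pieces at cutoff {cutoff} nm; "
            "no single set of box shifts reconnects it"
        )

    occupied = {tuple(v) for v in np.argwhere(mask)}
    start = next(iter(sorted(occupied)))
    shifts: dict[tuple[int, int, int], np.ndarray] = {start: np.zeros(3, dtype=np.int64)}
    queue = deque([start])
    shape = np.array(grid.shape)
    while queue:
        cur = queue.popleft()
        cshift = shifts[cur]
        for axis in range(3):
            for step in (-1, 1):
                nxt = list(cur)
                nxt[axis] += step
                carry = 0
                if nxt[axis] == shape[axis]:
                    nxt[axis] = 0
                    carry = 1
                elif nxt[axis] < 0:
                    nxt[axis] = shape[axis] - 1
                    carry = -1
                nxt = tuple(nxt)
                if nxt not in occupied:
                    continue
                nshift = cshift.copy()
                nshift[axis] += carry
                if nxt in shifts:
                    if not np.array_equal(shifts[nxt], nshift):
                        raise ReconstructionError(
                            "group wraps around the box (crosses the PBC multiple "
                            "times); cannot assign consistent shifts"
                        )
                else:
                    shifts[nxt] = nshift
                    queue.append(nxt)

    shift_field = np.zeros((*grid.shape, 3), dtype=np.int64)
    for vox, sh in shifts.items():
        shift_field[vox] = sh
    out = wrapped + shift_field[ijk[:, 0], ijk[:, 1], ijk[:, 2]] * box
    centroid = out.mean(axis=0)
    out -= np.floor(centroid / box) * box
    return out


# ---------------------------------------------------------------------------
# Leaflets
# ---------------------------------------------------------------------------

def leaflet_split(
    points: np.ndarray, centroid: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Partition linker sites into (outer, inner) leaflet index arrays.

    Sites are split by radial distance from the membrane centroid: the
    threshold is placed in the widest gap of the (mildly trimmed) sorted
    radius distribution, which is robust to the outer leaflet holding
    more lipids than the inner one — a plain median would then land
    inside the outer mode. Requires unwrapped coordinates of a
    vesicle-like (closed) membrane.
    """
    points = np.asarray(points, dtype=float)
    if len(points) < 2:
        raise GeometryError("need at least two linker sites to split leaflets")
    if centroid is None:
        centroid = points.mean(axis=0)
    r = np.linalg.norm(points - centroid, axis=1)
    if r.max() - r.min() < 1e-9:
        raise GeometryError("degenerate leaflet geometry: all radii equal")
    order = np.sort(r)
    trim = max(1, int(0.02 * len(r)))  # keep stray outliers from owning the gap
    lo = min(trim, len(r) - 2)
    hi = max(lo + 1, len(r) - trim)
    gaps = order[lo + 1 : hi] - order[lo : hi - 1]
    split = lo + int(np.argmax(gaps))
    threshold = 0.5 * (order[split] + order[split + 1])
    outer = np.flatnonzero(r > threshold)
    inner = np.flatnonzero(r <= threshold)
    return outer, inner


# ---------------------------------------------------------------------------
# Surfaces
# ---------------------------------------------------------------------------

def _convex_hull_backend(points: np.ndarray) -> tuple[float, float]:
    try:
        hull = ConvexHull(points)
    except QhullError as e:
        raise GeometryError(f"degenerate point set for surface reconstruction: {e}") from e
    return float(hull.area), float(hull.volume)


SURFACE_BACKENDS: dict[str, Callable[[np.ndarray], tuple[float, float]]] = {
    "convex_hull": _convex_hull_backend,
}


def surface_area_volume(
    points: np.ndarray, backend: str | Callable = "convex_hull"
) -> tuple[float, float]:
    """Area (nm^2) and enclosed volume (nm^3) of a closed surface through the points.

    The default backend triangulates the convex hull, which is exact for
    convex clouds; a callable taking the (N, 3) points and returning
    ``(area, volume)`` can be supplied for non-convex reconstruction.
    """
    points = np.asarray(points, dtype=float)
    if len(points) < 4:
        raise GeometryError(f"need >= 4 points for a closed surface, got {len(points)}")
    fn = SURFACE_BACKENDS[backend] if isinstance(backend, str) else backend
    area, volume = fn(points)
    if not (area > 0 and volume > 0):
        raise ReconstructionError(
            f"surface reconstruction returned a non-watertight result "
            f"(A={area}, V={volume})"
        )
    return area, volume


# ---------------------------------------------------------------------------
# Dimensionless descriptors
# ---------------------------------------------------------------------------

def reduced_volume(A_mid: float, V: float) -> float:
    """v = 6 sqrt(pi) V / A^(3/2); 1 for a sphere, scale-invariant."""
    if A_mid <= 0 or V <= 0:
        raise ParameterError(f"area and volume must be positive (A={A_mid}, V={V})")
    return 6.0 * math.sqrt(math.pi) * V / A_mid**1.5


def reduced_area_difference(A_out: float, A_in: float, thickness: float, A_mid: float) -> float:
    """da = (A_out - A_in) / (8 pi d R_A) with R_A = sqrt(A_mid / 4 pi).

    Exactly 1 for a sphere with leaflets at R +- d/2. The normalisation
    (factor and choice of mid-surface area) is an explicit argument so
    alternative conventions plug straight in.
    """
    if not (A_out > A_in > 0):
        raise InputError(f"leaflet areas must satisfy A_out > A_in > 0, got {A_out}, {A_in}")
    if thickness <= 0:
        raise ParameterError(f"thickness must be positive, got {thickness}")
    r_a = math.sqrt(A_mid / (4.0 * math.pi))
    return (A_out - A_in) / (8.0 * math.pi * thickness * r_a)


def gyration_eigenvalues(points: np.ndarray) -> np.ndarray:
    """Eigenvalues (descending, nm^2) of the gyration tensor about the centroid."""
    points = np.asarray(points, dtype=float)
    if len(points) < 4:
        raise GeometryError("need >= 4 points for the gyration tensor")
    x = points - points.mean(axis=0)
    tensor = x.T @ x / len(x)
    lam = np.linalg.eigvalsh(tensor)[::-1]
    if lam[0] <= 0:
        raise GeometryError("degenerate point cloud: all points identical")
    return lam


def asphericity(points: np.ndarray) -> float:
    """Gyration asphericity D in [0, 1]: 0 = sphere, 1 = thin rod."""
    l1, l2, l3 = gyration_eigenvalues(points)
    num = (l1 - l2) ** 2 + (l2 - l3) ** 2 + (l3 - l1) ** 2
    return float(num / (2.0 * (l1 + l2 + l3) ** 2))


def oblicity(points: np.ndarray) -> float:
    """Signed shape parameter S in [-0.25, 2]: oblate < 0 < prolate."""
    lam = gyration_eigenvalues(points)
    mean = lam.mean()
    return float(np.prod(lam - mean) / mean**3)


# ---------------------------------------------------------------------------
# Vesicle-level analysis
# ---------------------------------------------------------------------------

def radii_from_leaflets(
    outer_pts: np.ndarray, inner_pts: np.ndarray, centroid: np.ndarray
) -> tuple[float, float, float]:
    """Mean leaflet radii about the centroid and their difference (thickness)."""
    r_out = float(np.linalg.norm(outer_pts - centroid, axis=1).mean())
    r_in = float(np.linalg.norm(inner_pts - centroid, axis=1).mean())
    return r_out, r_in, r_out - r_in


def linker_sites(system: ParticleSystem, linker_names=("GL1", "GL2")) -> np.ndarray:
    """Indices of the membrane-group particles whose atom name is a linker."""
    membrane = np.asarray(system.groups["membrane"], dtype=np.int64)
    is_linker = np.isin(system.names[membrane], np.asarray(linker_names))
    sel = membrane[is_linker]
    if len(sel) == 0:
        raise InputError(f"no membrane particles named {linker_names} found")
    return sel


def radii_and_thickness(
    system: ParticleSystem,
    linker_names=("GL1", "GL2"),
    cutoff: float | None = None,
) -> tuple[float, float, float]:
    """(R_out, R_in, thickness) from the glycerol-linker sites of a vesicle."""
    whole = unwrap(system, system.groups["membrane"], cutoff=cutoff)
    membrane = np.asarray(system.groups["membrane"], dtype=np.int64)
    is_linker = np.isin(system.names[membrane], np.asarray(linker_names))
    pts = whole[is_linker]
    if len(pts) == 0:
        raise InputError(f"no membrane particles named {linker_names} found")
    outer, inner = leaflet_split(pts)
    return radii_from_leaflets(pts[outer], pts[inner], pts.mean(axis=0))


def analyze_vesicle(
    system: ParticleSystem,
    linker_names=("GL1", "GL2"),
    cutoff: float | None = None,
    backend: str | Callable = "convex_hull",
) -> ShapeMetrics:
    """Full shape record of a vesicle from its linker sites.

    Pipeline: make the membrane whole across PBC, split linker sites
    into leaflets, reconstruct a closed surface per leaflet, then derive
    the mid-surface area and enclosed volume by scale interpolation
    between the two leaflet surfaces (exact for concentric spheres) and
    evaluate the four dimensionless descriptors.
    """
    whole = unwrap(system, system.groups["membrane"], cutoff=cutoff)
    membrane = np.asarray(system.groups["membrane"], dtype=np.int64)
    is_linker = np.isin(system.names[membrane], np.asarray(linker_names))
    pts = whole[is_linker]
    if len(pts) == 0:
        raise InputError(f"no membrane particles named {linker_names} found")
    outer, inner = leaflet_split(pts)
    centroid = pts.mean(axis=0)
    r_out, r_in, d = radii_from_leaflets(pts[outer], pts[inner], centroid)
    a_out, v_out = surface_area_volume(pts[outer], backend=backend)
    a_in, v_in = surface_area_volume(pts[inner], backend=backend)
    a_mid = ((math.sqrt(a_out) + math.sqrt(a_in)) / 2.0) ** 2
    v_mid = ((v_out ** (1.0 / 3.0) + v_in ** (1.0 / 3.0)) / 2.0) ** 3
    return ShapeMetrics(
        A_out=a_out,
        A_in=a_in,
        A_mid=a_mid,
        V=v_mid,
        v=reduced_volume(a_mid, v_mid),
        da=reduced_area_difference(a_out, a_in, d, a_mid),
        asphericity=asphericity(pts),
        oblicity=oblicity(pts),
        R_out=r_out,
        R_in=r_in,
        thickness=d,
    )


def shape_trajectory(records: list[ShapeMetrics], cycles=None) -> pd.DataFrame:
    """Ordered per-cycle table of the shape descriptors (the shape-diagram data)."""
    if len(records) == 0:
        raise InputError("need at least one shape record")
    if cycles is None:
        cycles = list(range(len(records)))
    rows = [
        dict(
            cycle=c,
            v=m.v,
            da=m.da,
            asphericity=m.asphericity,
            oblicity=m.oblicity,
            V=m.V,
            A=m.A_mid,
            R_out=m.R_out,
            R_in=m.R_in,
            thickness=m.thickness,
        )
        for c, m in zip(cycles, records)
    ]
    return pd.DataFrame(rows)
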