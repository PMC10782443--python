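# Methods

This note documents the models, parameters and numerical choices behind
`osmopump`, and what the synthetic test systems do and do not establish
about behaviour on real simulation data.

## The pumping model

An osmotic shock is emulated by relocating solvent molecules between the
two solvent compartments separated by a closed membrane, a fixed number
per cycle, with a production run of the user's simulation engine in
between. The protocol assumes:

- an **orthorhombic** periodic box (triclinic cells are rejected at the
  I/O boundary);
- exactly **two compartments** — one enclosed, one bulk. Multilamellar
  systems transiently yielding three or more solvent clusters make the
  controller refuse to pump with a diagnostic rather than guess which
  cluster to drain;
- an index file that puts *everything residing in the membrane*
  (lipids, sterols, embedded proteins) in the `membrane` group and *only
  relocatable solvent* in the `solvent` group. Ions, polymers and
  soluble proteins are neither: they never influence the bin labels, but
  they are tracked as "solute" so relocation avoids their hydration
  shells.

### Voxelisation

Bin counts are `n = max(1, round(l / edge))` per axis with the actual
edge `l / n`, so bins tile the box exactly whatever the requested edge.
The default edge of 1.3 nm balances two failure modes: smaller bins
resolve the membrane surface better (fewer near-surface waters counted as
membrane-bin residents) but raise the chance of a spuriously
non-contiguous membrane voxel structure, which makes all solvent one
cluster and halts pumping. Positions are always wrapped into `[0, l)`
before binning — engines emit unwrapped coordinates — and multi-site
molecules are binned by their first particle (the reference site); for
monatomic coarse-grained water that is the particle itself. Binning all
sites of a multi-site solvent instead would split molecules across bins
and complicate the one-molecule-per-bin bookkeeping for no benefit at
these bin sizes.

### Compartment identification

Solvent bins are clustered under strict face (6-)connectivity with
wrapping at all box faces. The implementation labels components with
`scipy.ndimage.label` and then merges labels that touch across opposite
faces using a union–find pass; ids are renumbered by first appearance in
a C-order scan so runs are reproducible. A hand-written breadth-first
flood fill — sharing no code with this path — serves as the test oracle
and must agree bin-for-bin on randomised occupancy fields.

The bulk compartment is the cluster owning the most of the eight corner
bins. A tie, or all corners being membrane, is raised as a hard error
advising recentring: the corner heuristic genuinely breaks down when the
enclosed object crosses a box corner under periodicity, and silently
picking a side would swap the pumping direction.

### Relocation

Source bins are drawn uniformly without replacement from the source
compartment, solvent-only bins first and solute-containing bins only when
the solvent-only pool is exhausted; one molecule per bin disperses the
perturbation. The insertion point is the best of `n_trials` uniform
candidates in the target bin shrunk by `margin` on every face, scoring
each candidate by its minimum-image distance to every particle in the
bin and its 26 neighbours. Defaults: `margin = 0.3 nm` (interpreted as an
*inner* margin — its purpose is clearance from particles in neighbouring
bins, which an outer margin would not provide) and `n_trials = 100`,
which on the bundled fixtures yields clearances above 0.2 nm in ≥ 99% of
insertions at CG water density. A poor clearance is reported, not raised;
whether to retry is the controller's decision via its recovery path.
Moves are rigid translations placing the reference site on the insertion
point: intramolecular geometry and all velocities are preserved
bit-for-bit, and molecule counts never change, so the topology file stays
valid across arbitrarily many cycles.

### Controller

One shared `numpy` generator seeded from the config drives every
stochastic choice, so a run is replayable bit-for-bit from
`(config, seed, engine)`. Per cycle, the monitoring record keeps the
enclosed solvent count, the coarse inner volume (inner-bin count × bin
volume) and the interior solute concentration (inner-bin solute count /
Avogadro / coarse volume in litres; a surface-based volume can be passed
instead when shape analysis is running).

Steady-state mode records the enclosed count at entry as the baseline
and corrects once per `steady_window` (default 10) cycles by
`round(baseline − window mean)`, executed as a single burst at the window
end. The windowed average exists because solvent near the membrane
surface flickers between membrane bins (not counted) and compartment
bins (counted) from cycle to cycle; correcting on instantaneous counts
would overcompensate and itself deform the membrane. The correction keys
on the *count*, not the coarse volume: the count is what relocation
changes directly and is integer-exact, while the coarse volume moves in
whole-bin quanta. Target switching (`target_volume` /
`target_concentration`) flips a shock run into steady-state mode when the
monitored value crosses the target in the shock direction.

Rupture (a single solvent cluster for a system configured to enclose
one) suspends pumping for a healing run of `healing_time` (default
500 ns) and repeats until clustering again finds two compartments. An
engine failure restores the full pre-relocation checkpoint (one snapshot
retained), draws a fresh plan with the advanced RNG state and retries,
up to `max_retries` (default 5) before terminating with the last error.
Optional pre-equilibration (e.g. 20 ps at a 2 fs timestep) runs between
relocation and production — useful when rising internal pressure makes
insertions tight.

## Shape analysis

All four descriptors are computed in one place (`shapes.py`) so swapping
a normalisation is a one-line change:

- `v = 6√π V / A_mid^{3/2}`;
- `Δa = (A_out − A_in) / (8π d R_A)` with `R_A = √(A_mid/4π)` and `d`
  the measured leaflet-radius difference. The normalisation makes a
  sphere with leaflets at `R ± d/2` exactly `(v, Δa) = (1, 1)`, the
  anchor every variant of this diagram shares. `A_mid` is an explicit
  argument, so alternative mid-surface conventions plug in directly;
- `Δ` and `S` from the gyration-tensor eigenvalues with the bounds
  `Δ ∈ [0,1]`, `S ∈ [−0.25, 2]` (disk → −0.25, rod → 2).

Pipeline choices:

- **Unwrapping** voxelises the group at 1.5× the default bin edge and
  flood-fills the occupied voxels across the boundaries, accumulating an
  integer box shift per voxel. Two failure modes are raised explicitly
  rather than silently misassembled: a group that is disconnected at the
  cutoff, and a group that wraps all the way around the box (the shift
  assignment becomes inconsistent).
- **Leaflet splitting** thresholds linker-site radii (about the linker
  centroid) at the widest gap of the sorted radius distribution, trimmed
  by 2% per tail so stray outliers cannot own the gap. A plain median
  threshold fails even for perfect concentric shells because the outer
  leaflet holds more lipids (≈ the leaflet area ratio), putting the
  median inside the outer mode. The gap rule requires the inter-leaflet
  gap to dominate the radial noise, which holds for resolvable bilayers;
  strongly non-spherical vesicles blur the radial modes and are the
  known weak spot (see Limitations).
- **Surfaces** default to the convex hull (`scipy.spatial.ConvexHull`):
  exact for convex clouds, which the validation fixtures are. Non-convex
  backends are pluggable as callables returning `(area, volume)`; any
  non-watertight result (non-positive area or volume) is raised as a
  reconstruction error.
- **Mid-surface area and volume** are scale-interpolated between the
  leaflet hulls, `A_mid = ((√A_out + √A_in)/2)²` and
  `V = ((V_out^{1/3} + V_in^{1/3})/2)³` — exact for concentric spheres
  and second-order accurate for mild deformations.
- The **membrane centroid** for radii is the linker-site centroid; for
  strongly non-spherical vesicles mean leaflet radii lose geometric
  meaning and `Δ`, `S`, `v` are the meaningful descriptors.

## Synthetic fixtures and what they show

The generators build the three canonical topologies from deterministic
lattices: vesicles as concentric Fibonacci-sphere shells (linker shells
at `r_mid ± thickness/2`, filler shells every ≤ 0.55 nm so the membrane
is voxel-contiguous at the default bin edge), a spherical-cap pore of
arc radius ≥ 2 bin edges for the rupture path, and planar double
bilayers whose central gap is the enclosed compartment. Solvent sits on
a jittered cubic lattice at 8.3 beads/nm³ (bulk coarse-grained water,
four waters per bead); optional Na/Cl pairs go in the exterior. Every
fixture is bit-reproducible from its seed.

The mock engines bracket the protocol logic, not the physics: *identity*
(no motion — exact bookkeeping), *Brownian* (Gaussian jitter, membrane
frozen), *leaky* (Brownian plus 0–3 randomly chosen interior waters
displaced to the exterior per production run — the permeation signal the
steady-state controller must cancel). The Brownian mock treats
membrane-occupied voxels as a hard wall, rejecting jitter moves that
would land inside them: with no interaction forces, a free random walk
slowly floods the empty membrane voxel zone, a flux a real (impermeable
on these timescales) bilayer forbids and one that would contaminate the
leak signal the controller is being tested against.

Passing tests on these fixtures demonstrates the protocol's *logic*:
exact conservation and per-cycle accounting, correct periodic
segmentation, insertion clearance guarantees, control-loop stability and
bit-level replayability. They do not demonstrate thermodynamic fidelity
of any engine, realistic membrane mechanics, or shape evolution under
real forces — those depend on the external engine the adapter connects.

## Numerical notes

- Wrapped coordinates are clipped to the last bin index to absorb the
  one-ulp case where `wrapped/edge` rounds up to `n`; the brute-force
  test oracle uses `floor` of the rounded quotient for the same reason
  (float `//` can disagree by one ulp exactly on a bin boundary).
- Clearance against an empty neighbourhood is reported as `+inf`, never
  an error.
- Degenerate inputs raise typed errors throughout (`GeometryError`,
  `ReconstructionError`, `AmbiguousOuterError`, ...) rather than
  returning sentinel values.
- Problem sizes in the test suite and acceptance script: ~64,000-particle
  vesicle fixtures (20 nm box), 100-cycle control runs, 12³ random
  clustering fields, 5,000–20,000-point shape clouds. These sizes were
  chosen so the whole validation pipeline exercises every code path at
  full fidelity while remaining a desk-scale computation.

## Known limitations

- Two compartments only; multilamellar topologies need a finer
  segmentation than binary membrane/solvent voxels.
- Rectangular boxes only.
- Unwrapping fails (loudly) for objects crossing the periodic boundary
  in a way that admits no single set of box shifts.
- The convex-hull surface underestimates area for strongly non-convex
  (e.g. stomatocyte) shapes; plug in a non-convex backend for those.
- The leaflet split assumes a radially resolvable bilayer about a single
  centroid.
- The relocation plan scores candidates against the pre-move
  configuration; two molecules inserted into the same bin in one cycle
  are not scored against each other. At the default one-molecule-per-bin
  selection and CG densities this has not produced sub-margin contacts.
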