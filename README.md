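# osmopump

Controlled osmotic-shock simulation for particle-based membrane systems,
plus vesicle shape analysis — without waiting for water to permeate.

## The problem

Letting an explicit osmotic shock develop by passive permeation through a
lipid bilayer is hopeless at molecular-dynamics timescales: a 16 nm
vesicle holds ~150,000 water particles and sheds them at ~1000 permeation
events per μs, so a 50% volume reduction would need on the order of 75 μs
of simulation — before accounting for counter-flux. `osmopump` implements
the standard remedy: *pump* the solvent instead. Each cycle it

1. voxelises the box into bins (default edge 1.3 nm) and marks every bin
   that holds a membrane particle,
2. clusters the remaining solvent bins into connected compartments with a
   6-connected flood fill that wraps across periodic boundaries, and
   identifies the bulk compartment as the one owning most of the eight
   box-corner bins,
3. picks bins at random from the source compartment (preferring bins with
   no solute, so hydration shells stay untouched), one molecule per bin,
4. re-inserts each molecule at the best of `n_trials` random points in a
   target-compartment bin — maximising the minimum-image distance to all
   particles in the bin and its 26 neighbours, keeping a 0.3 nm margin
   from the bin faces — with velocities preserved,
5. hands the system to the simulation engine for a production run.

A hypertonic shock moves solvent inner → outer, a hypotonic shock the
reverse. **Steady-state mode** holds the enclosed solvent count at a
baseline, correcting once per 10-cycle window by `round(baseline − window
mean)` so that solvent flickering in and out of membrane bins is not
overcompensated. If the membrane ruptures (all solvent becomes one
compartment), pumping stops and a healing run (default 500 ns) is
performed until contiguity returns. Engine failures restore the
pre-relocation checkpoint and retry with a fresh plan (bounded retries).

The MD engine is abstracted behind a one-method interface, so the entire
protocol is testable with the bundled mock engines (identity, Brownian,
leaky); a thin subprocess adapter (`ExternalEngine`) connects a real
engine.

## Shape descriptors

Vesicle deformation is tracked per cycle with the standard dimensionless
descriptors, computed from the glycerol-linker sites after making the
membrane whole across periodic boundaries:

- reduced volume `v = 6√π · V / A^{3/2}` (1 = sphere, < 1 = deflated),
- reduced area difference `Δa = (A_out − A_in) / (8π d R_A)`,
  `R_A = √(A_mid/4π)` (1 = sphere),
- asphericity `Δ = [(λ₁−λ₂)² + (λ₂−λ₃)² + (λ₃−λ₁)²] / [2(λ₁+λ₂+λ₃)²]`
  from the gyration-tensor eigenvalues (0 = sphere, 1 = thin rod),
- oblicity `S = Πᵢ(λᵢ−λ̄)/λ̄³` (−0.25 = thin disk ≤ S ≤ 2 = thin rod).

Leaflet surfaces are reconstructed with a pluggable backend (convex hull
by default; exact for convex clouds). The per-cycle `(v, Δa)` table is
the classic vesicle shape diagram.

## Worked example

```python
import osmopump as op
from osmopump import controller as ctl
from osmopump.grid import bin_contents

vesicle = op.make_vesicle(r_mid=6.0, thickness=2.0, seed=0)
config = ctl.ShockConfig(direction="hypertonic", rate=10, cycle_time=2.0, seed=42)
final, state = ctl.run_pumping(vesicle, config, ctl.IdentityEngine(), n_cycles=20)

grid = op.make_grid(final.box, 1.3)
cmap = op.assign_roles(op.cluster_solvent(op.label_bins(final, grid)), grid)
print("enclosed waters:", state.history[0]["enclosed"], "->",
      op.count_enclosed_solvent(cmap, bin_contents(final, grid)))

m = op.analyze_vesicle(final)
print(f"reduced volume v: {m.v:.4f}   area difference da: {m.da:.4f}")
print(f"leaflet radii: {m.R_out:.2f} / {m.R_in:.2f} nm")

rate_per_us = 2000 / 2.0
print("passive permeation would need:",
      ctl.estimate_passive_permeation_time(150_000, rate_per_us, 0.5), "us")
```

prints

```
enclosed waters: 2385 -> 2185
reduced volume v: 0.9993   area difference da: 1.0009
leaflet radii: 7.00 / 5.00 nm
passive permeation would need: 75.0 us
```

Twenty cycles at 10 molecules per cycle remove exactly 200 enclosed
waters (the identity engine adds no motion of its own), the vesicle stays
spherical (`v ≈ 1`, `Δa ≈ 1`), and the leaflet radii are the fixture's
construction values — while the passive-permeation estimate shows why
pumping is needed in the first place.

The same run from the shell:

```sh
osmopump fixtures make-vesicle --out fx
osmopump pump --gro fx/vesicle.gro --ndx fx/vesicle.ndx --top fx/vesicle.top \
    --mode hyper --rate 10 --cycles 20 --engine identity --seed 42 --out run
osmopump analyze --gro run/final.gro --ndx fx/vesicle.ndx --out run/metrics.tsv
```

`run/history.tsv` records cycle, mode, enclosed count, coarse inner
volume, interior solute concentration, moves and retries per cycle.

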