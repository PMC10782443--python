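"""Pumping-cycle orchestration: shocks, steady state, healing, recovery.

A pumping run is a loop of cycles. Each cycle voxelises the box, clusters
the solvent bins into compartments, relocates ``rate`` solvent molecules
along the shock direction (inner -> outer for a hypertonic shock, outer ->
inner for hypotonic), optionally pre-equilibrates, and hands the system to
the simulation engine for a production run.

Beyond plain shocks the controller supports:

* **steady-state mode** — holds the enclosed solvent count at the baseline
  recorded on entry, correcting once per averaging window (default 10
  cycles) by the rounded difference between baseline and window mean, so
  solvent that merely wanders in and out of membrane bins does not cause
  overcompensation;
* **target switching** — an optional target interior volume or solute
  concentration flips a shock run into steady-state mode once crossed;
* **healing** — if the membrane has ruptured (all solvent one compartment)
  the cycle performs a no-pumping healing run (default 500 ns) and resumes
  only when contiguity returns;
* **failure recovery** — if the engine fails, the pre-relocation checkpoint
  is restored and a fresh plan is drawn with advanced RNG state, up to a
  bounded number of retries.

The engine is abstracted behind a tiny contract (`run(system, duration_ns,
timestep_fs)` returning a system with an identical particle inventory);
mock engines for testing (identity, Brownian, leaky) live here too.
"""

from __future__ import annotations

import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import compartments as cpt
from .compartments import CompartmentMap, assign_roles, cluster_solvent, detect_rupture
from .errors import (
    EngineFailure,
    MultiCompartmentError,
    ParameterError,
    SolventExhaustedError,
    StateError,
)
from .grid import BinContents, GridSpec, bin_contents, label_bins, make_grid
from .relocation import RelocationPlan, apply_relocation, plan_relocation
from .sysio import ParticleSystem, write_gro

AVOGADRO = 6.02214076e23
NM3_TO_L = 1e-24

HYPERTONIC = "hypertonic"
HYPOTONIC = "hypotonic"
STEADY = "steady"

MODE_PUMPING = "pumping"
MODE_STEADY = "steady"
MODE_HEALING = "healing"
MODE_TERMINATED = "terminated"


@dataclass
class ShockConfig:
    """User-facing knobs of a pumping run.

    rate is in molecules per cycle; cycle_time in ns of production per
    cycle; bin_edge / margin in nm. ``pre_equilibration`` is either None
    or a (duration_ps, timestep_fs) pair executed right after relocation
    (useful when rising internal pressure causes insertion overlap).
    Exactly one of the optional targets may be set.
    """

    direction: str = HYPERTONIC
    rate: int = 10
    cycle_time: float = 2.0
    bin_edge: float = 1.3
    margin: float = 0.3
    n_trials: int = 100
    pre_equilibration: tuple[float, float] | None = None
    target_volume: float | None = None
    target_concentration: float | None = None
    healing_time: float = 500.0
    steady_window: int = 10
    max_retries: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.direction not in (HYPERTONIC, HYPOTONIC, STEADY):
            raise ParameterError(f"unknown direction {self.direction!r}")
        if self.direction != STEADY and self.rate < 1:
            raise ParameterError("rate must be >= 1 for pumping modes")
        if self.target_volume is not None and self.target_concentration is not None:
            raise ParameterError("set at most one of target_volume / target_concentration")
        if self.steady_window < 1:
            raise ParameterError("steady_window must be >= 1")


@dataclass
class PumpState:
    """Mutable per-run state: cycle counter, mode, monitoring history."""

    cycle: int = 0
    mode: str = MODE_PUMPING
    history: list[dict] = field(default_factory=list)
    baseline: int | None = None
    window_counts: list[int] = field(default_factory=list)
    _resume_mode: str = MODE_PUMPING


# ---------------------------------------------------------------------------
# Engines
# ---------------------------------------------------------------------------

class Engine:
    """Contract: advance the system; never create or destroy particles."""

    def run(
        self, system: ParticleSystem, duration_ns: float, timestep_fs: float | None = None
    ) -> ParticleSystem:
        raise NotImplementedError


class IdentityEngine(Engine):
    """No motion at all — the bookkeeping reference engine."""

    def run(self, system, duration_ns, timestep_fs=None):
        return system


class BrownianEngine(Engine):
    """Gaussian positional jitter of non-membrane particles; membrane frozen.

    Displacement per call is N(0, sigma * sqrt(duration_ns)) per
    coordinate — enough stochastic motion to exercise re-binning and
    clustering, with no pretence of real dynamics. The membrane acts as a
    hard wall at voxel resolution: a trial displacement that would land a
    particle inside a membrane-occupied voxel is rejected (position kept),
    since without interaction forces solvent would otherwise slowly invade
    the membrane interior, which an impermeable bilayer forbids.
    """

    def __init__(self, sigma: float = 0.05, seed: int = 0, bin_edge: float = 1.3):
        self.sigma = sigma
        self.bin_edge = bin_edge
        self.rng = np.random.default_rng(seed)

    def run(self, system, duration_ns, timestep_fs=None):
        out = system.copy()
        frozen = np.zeros(system.n_particles, dtype=bool)
        frozen[system.groups.get("membrane", np.empty(0, dtype=np.int64))] = True
        mobile = np.flatnonzero(~frozen)
        if mobile.size == 0:
            return out
        scale = self.sigma * np.sqrt(max(duration_ns, 0.0))
        trial = out.positions[mobile] + self.rng.normal(0.0, scale, size=(mobile.size, 3))
        grid = make_grid(out.box, self.bin_edge)
        labels = label_bins(out, grid)
        from .grid import MEMBRANE, bin_index

        ijk = bin_index(trial, grid)
        blocked = labels.labels[ijk[:, 0], ijk[:, 1], ijk[:, 2]] == MEMBRANE
        accepted = mobile[~blocked]
        out.positions[accepted] = trial[~blocked]
        return out


class LeakyEngine(BrownianEngine):
    """Brownian jitter plus forced loss of interior solvent.

    Each production run, 0..max_leak randomly chosen solvent molecules of
    the inner compartment are displaced into the outer compartment —
    emulating passive permeation so that steady-state control has
    something to counteract.
    """

    def __init__(self, sigma: float = 0.02, max_leak: int = 3, bin_edge: float = 1.3, seed: int = 0):
        super().__init__(sigma=sigma, seed=seed, bin_edge=bin_edge)
        self.max_leak = max_leak

    def run(self, system, duration_ns, timestep_fs=None):
        out = super().run(system, duration_ns, timestep_fs)
        n_leak = int(self.rng.integers(0, self.max_leak + 1))
        if n_leak == 0:
            return out
        grid = make_grid(out.box, self.bin_edge)
        labels = label_bins(out, grid)
        cmap = cluster_solvent(labels)
        if cmap.n_clusters != 2:
            return out  # ruptured or odd topology: nothing to leak through
        cmap = assign_roles(cmap, grid)
        contents = bin_contents(out, grid)
        flat_ids = cmap.cluster_id.ravel()
        inner_mask = flat_ids[contents.solvent_flat_bins] == cmap.inner_id
        inner_mols = contents.solvent_mol_ids[inner_mask]
        outer_bins = np.flatnonzero(flat_ids == cmap.outer_id)
        if inner_mols.size == 0 or outer_bins.size == 0:
            return out
        n_leak = min(n_leak, inner_mols.size)
        mols = self.rng.choice(inner_mols, size=n_leak, replace=False)
        for mol in mols:
            a, z = out.molecules[mol]
            dest = grid.unflatten(int(self.rng.choice(outer_bins)))
            point = grid.bin_center(dest) + self.rng.uniform(-0.2, 0.2, 3) * grid.edges
            out.positions[a:z] += point - out.positions[a]
        return out


class FailingEngine(Engine):
    """Fails the first ``fail_times`` runs, then delegates — recovery-path mock."""

    def __init__(self, fail_times: int, inner: Engine | None = None):
        self.fail_times = fail_times
        self.calls = 0
        self.inner = inner or IdentityEngine()

    def run(self, system, duration_ns, timestep_fs=None):
        self.calls += 1
        if self.calls <= self.fail_times:
            raise EngineFailure(f"mock engine failure on call {self.calls}")
        return self.inner.run(system, duration_ns, timestep_fs)


class ExternalEngine(Engine):
    """Thin subprocess adapter to a real MD engine.

    The command is invoked as ``cmd <in.gro> <out.gro> <duration_ns>
    [<timestep_fs>]``; it must write the advanced configuration to
    ``out.gro`` with an unchanged particle inventory. A non-zero exit
    raises :class:`EngineFailure`, which routes into the controller's
    recovery path. Not exercised by the test suite.
    """

    def __init__(self, command: str):
        self.command = command

    def run(self, system, duration_ns, timestep_fs=None):
        from .sysio import read_gro

        with tempfile.TemporaryDirectory() as tmp:
            inp = Path(tmp) / "in.gro"
            outp = Path(tmp) / "out.gro"
            write_gro(system, inp)
            args = [self.command, str(inp), str(outp), str(duration_ns)]
            if timestep_fs is not None:
                args.append(str(timestep_fs))
            proc = subprocess.run(args, capture_output=True, text=True)
            if proc.returncode != 0:
                raise EngineFailure(
                    f"external engine exited {proc.returncode}: {proc.stderr[-500:]}"
                )
            advanced = read_gro(outp)
        if advanced.n_particles != system.n_particles:
            raise EngineFailure("external engine changed the particle inventory")
        out = system.copy()
        out.positions = advanced.positions
        if advanced.velocities is not None:
            out.velocities = advanced.velocities
        out.box = advanced.box
        return out


# ---------------------------------------------------------------------------
# Monitoring utilities
# ---------------------------------------------------------------------------

def interior_concentration(
    system: ParticleSystem,
    cmap: CompartmentMap,
    grid: GridSpec,
    contents: BinContents | None = None,
    volume_nm3: float | None = None,
) -> float:
    """Molar concentration of solute in the inner compartment, mol/L.

    Solute particles assigned to inner-compartment bins are divided by
    the coarse (bin-count) inner volume; pass ``volume_nm3`` to use a
    surface-based volume from the shape analysis instead.
    """
    if cmap.inner_id is None:
        raise StateError("inner compartment undefined; cannot compute concentration")
    if contents is None:
        contents = bin_contents(system, grid)
    flat_ids = cmap.cluster_id.ravel()
    n_solute = int(np.count_nonzero(flat_ids[contents.solute_flat_bins] == cmap.inner_id))
    if volume_nm3 is None:
        volume_nm3 = cpt.compartment_volume(cmap, grid, cmap.inner_id)
    return n_solute / AVOGADRO / (volume_nm3 * NM3_TO_L)


def estimate_passive_permeation_time(
    n_interior: float, permeation_rate: float, fraction: float
) -> float:
    """Back-of-envelope time (μs) for passive permeation to shed solvent.

    ``fraction * n_interior / permeation_rate`` with the rate in events
    per μs. This is the classic motivation for active pumping: a 16 nm
    vesicle holding ~150,000 waters at ~1000 permeation events/μs needs
    75 μs of simulation for a 50% volume reduction — and that ignores
    counter-flux and the decaying osmotic pressure, so realistic times
    are longer still.
    """
    if permeation_rate <= 0:
        raise ParameterError(f"permeation rate must be positive, got {permeation_rate}")
    if not 0.0 <= fraction <= 1.0:
        raise ParameterError(f"fraction must be in [0, 1], got {fraction}")
    return fraction * n_interior / permeation_rate


# ---------------------------------------------------------------------------
# Control logic
# ---------------------------------------------------------------------------

def steady_state_update(state: PumpState, config: ShockConfig) -> int:
    """Signed correction at window boundaries; 0 mid-window.

    Once ``steady_window`` cycle counts have accumulated, returns
    ``round(baseline - window_mean)`` (positive: pump inward) and resets
    the window. Averaging absorbs the solvent that flickers between
    membrane and compartment bins from cycle to cycle.
    """
    if state.baseline is None:
        raise StateError("steady-state baseline not recorded")
    if len(state.window_counts) < config.steady_window:
        return 0
    mean = float(np.mean(state.window_counts[-config.steady_window :]))
    state.window_counts = []
    return int(round(state.baseline - mean))


def check_targets(state: PumpState, config: ShockConfig, volume: float, concentration: float | None) -> str:
    """Mode-transition table for target crossing.

    pumping -> steady when the target volume (or concentration) is
    crossed in the shock direction; otherwise the mode is unchanged.
    Rupture and termination transitions are handled by the cycle driver.
    """
    if state.mode != MODE_PUMPING:
        return state.mode
    if config.target_volume is not None:
        crossed = (
            volume <= config.target_volume
            if config.direction == HYPERTONIC
            else volume >= config.target_volume
        )
        if crossed:
            return MODE_STEADY
    if config.target_concentration is not None and concentration is not None:
        crossed = (
            concentration >= config.target_concentration
            if config.direction == HYPERTONIC
            else concentration <= config.target_concentration
        )
        if crossed:
            return MODE_STEADY
    return state.mode


def recover(
    system_checkpoint: ParticleSystem,
    state: PumpState,
    config: ShockConfig,
    rng: np.random.Generator,
    attempt,
) -> tuple[ParticleSystem, int]:
    """Bounded retry loop around a failed cycle attempt.

    Restores the pre-relocation checkpoint, lets ``attempt`` draw a fresh
    plan with the (advanced) RNG and re-run the engine. After
    ``config.max_retries`` consecutive failures the run is terminated
    with the last error attached.
    """
    last: Exception | None = None
    for retry in range(1, config.max_retries + 1):
        try:
            return attempt(system_checkpoint.copy(), rng), retry
        except EngineFailure as e:
            last = e
    state.mode = MODE_TERMINATED
    raise EngineFailure(
        f"cycle {state.cycle}: engine failed {config.max_retries} retries"
    ) from last


def _rng_fingerprint(rng: np.random.Generator) -> int:
    st = rng.bit_generator.state["state"]
    return int(st["state"] % (2**63))


def run_cycle(
    system: ParticleSystem,
    state: PumpState,
    config: ShockConfig,
    engine: Engine,
    rng: np.random.Generator,
) -> tuple[ParticleSystem, PumpState]:
    """One full pumping cycle: bin, cluster, relocate, (equilibrate,) run.

    If the membrane is ruptured at cycle start, no pumping happens; a
    healing run of ``config.healing_time`` ns is performed instead and
    the previous mode resumes once contiguity is back. Engine failures
    route through :func:`recover`.
    """
    if state.mode not in (MODE_PUMPING, MODE_STEADY, MODE_HEALING):
        raise StateError(f"cannot run a cycle in mode {state.mode!r}")

    grid = make_grid(system.box, config.bin_edge)
    labels = label_bins(system, grid)
    cmap = cluster_solvent(labels)

    if detect_rupture(cmap):
        if state.mode != MODE_HEALING:
            state._resume_mode = state.mode
        state.mode = MODE_HEALING
        system = engine.run(system, config.healing_time)
        post = cluster_solvent(label_bins(system, make_grid(system.box, config.bin_edge)))
        healed = post.n_clusters == 2
        if healed:
            state.mode = state._resume_mode
        state.history.append(
            dict(
                cycle=state.cycle,
                mode=MODE_HEALING,
                enclosed=-1,
                inner_volume_nm3=float("nan"),
                concentration_M=float("nan"),
                moves=0,
                retries=0,
                rng_state=_rng_fingerprint(rng),
            )
        )
        state.cycle += 1
        return system, state

    if cmap.n_clusters > 2:
        raise MultiCompartmentError(
            f"cycle {state.cycle}: {cmap.n_clusters} solvent compartments found; "
            "pumping supports exactly two (a transiently detached solvent pocket "
            "or a multilamellar system) — refusing to pump"
        )
    if state.mode == MODE_HEALING:  # membrane is whole again
        state.mode = state._resume_mode
    cmap = assign_roles(cmap, grid)
    contents = bin_contents(system, grid)
    enclosed = cpt.count_enclosed_solvent(cmap, contents)
    volume = cpt.compartment_volume(cmap, grid, cmap.inner_id)
    conc = interior_concentration(system, cmap, grid, contents)

    new_mode = check_targets(state, config, volume, conc)
    if new_mode == MODE_STEADY and state.mode == MODE_PUMPING:
        state.mode = MODE_STEADY
        state.baseline = enclosed
        state.window_counts = []

    if state.mode == MODE_STEADY:
        if state.baseline is None:
            state.baseline = enclosed
        state.window_counts.append(enclosed)
        correction = steady_state_update(state, config)
        k = abs(correction)
        inward = correction > 0
    else:
        k = config.rate
        inward = config.direction == HYPOTONIC
    src, dst = (
        (cmap.outer_id, cmap.inner_id) if inward else (cmap.inner_id, cmap.outer_id)
    )

    checkpoint = system.copy()

    def attempt(sys_in: ParticleSystem, rng_: np.random.Generator) -> ParticleSystem:
        if k > 0:
            plan = plan_relocation(
                sys_in, grid, cmap, contents, k, src, dst, rng_,
                margin=config.margin, n_trials=config.n_trials,
            )
            attempt.last_plan = plan
            sys_out = apply_relocation(sys_in, plan)
        else:
            attempt.last_plan = RelocationPlan()
            sys_out = sys_in
        if config.pre_equilibration is not None:
            dur_ps, ts_fs = config.pre_equilibration
            sys_out = engine.run(sys_out, dur_ps * 1e-3, ts_fs)
        return engine.run(sys_out, config.cycle_time)

    retries = 0
    try:
        system = attempt(checkpoint.copy(), rng)
    except EngineFailure:
        system, retries = recover(checkpoint, state, config, rng, attempt)
    except SolventExhaustedError:
        state.mode = MODE_TERMINATED
        raise

    state.history.append(
        dict(
            cycle=state.cycle,
            mode=state.mode,
            enclosed=enclosed,
            inner_volume_nm3=volume,
            concentration_M=conc,
            moves=len(attempt.last_plan),
            retries=retries,
            rng_state=_rng_fingerprint(rng),
        )
    )
    state.cycle += 1
    return system, state


def run_pumping(
    system: ParticleSystem,
    config: ShockConfig,
    engine: Engine,
    n_cycles: int,
    out_dir: str | Path | None = None,
    snapshot_every: int = 0,
) -> tuple[ParticleSystem, PumpState]:
    """Drive ``n_cycles`` pumping cycles and optionally write outputs.

    With ``out_dir`` set, writes ``history.tsv`` (one row per cycle), the
    final configuration ``final.gro`` and, if ``snapshot_every`` > 0,
    per-cycle GRO snapshots. Identical config + seed + engine reproduce
    the run bit-for-bit.
    """
    import pandas as pd

    rng = np.random.default_rng(config.seed)
    state = PumpState(mode=MODE_STEADY if config.direction == STEADY else MODE_PUMPING)
    state._resume_mode = state.mode
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)
    for _ in range(n_cycles):
        try:
            system, state = run_cycle(system, state, config, engine, rng)
        except SolventExhaustedError:
            break
        if out_path is not None and snapshot_every and state.cycle % snapshot_every == 0:
            write_gro(system, out_path / f"cycle_{state.cycle:05d}.gro")
        if state.mode == MODE_TERMINATED:
            break
    if state.mode != MODE_TERMINATED:
        state.mode = MODE_TERMINATED
    if out_path is not None:
        pd.DataFrame(state.history).to_csv(out_path / "history.tsv", sep="\t", index=False)
        write_gro(system, out_path / "final.gro")
    return system, state
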