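"""Source selection, trial insertion and molecule relocation."""

import numpy as np
import pytest

import osmopump as op
from osmopump.compartments import assign_roles, cluster_solvent
from osmopump.errors import ParameterError, SolventExhaustedError, StateError
from osmopump.grid import bin_contents
from osmopump.relocation import (
    Move,
    RelocationPlan,
    apply_relocation,
    choose_target_bin,
    find_molecules_in_bins,
    gather_nearby,
    insertion_point,
    min_image_distances,
    plan_relocation,
    select_source_bins,
)
from osmopump.sysio import ParticleSystem, molecules_from_resids


@pytest.fixture()
def shell_scene(make_boxed_shell):
    """Cubic shell with 200 interior waters, clustered and ready."""
    sys_, n_inner_bins = make_boxed_shell(inner_waters=200, seed=1)
    grid = op.make_grid(sys_.box, 1.3)
    cmap = assign_roles(cluster_solvent(op.label_bins(sys_, grid)), grid)
    contents = bin_contents(sys_, grid)
    return sys_, grid, cmap, contents


class TestSelectSourceBins:
    def test_deterministic_under_seed(self, shell_scene):
        _, _, cmap, contents = shell_scene
        a, _ = select_source_bins(cmap, contents, 10, np.random.default_rng(5), cmap.inner_id)
        b, _ = select_source_bins(cmap, contents, 10, np.random.default_rng(5), cmap.inner_id)
        assert a == b
        assert len(set(a)) == 10

    def test_bins_hold_solvent_and_lie_in_source(self, shell_scene):
        _, grid, cmap, contents = shell_scene
        bins, shortfall = select_source_bins(
            cmap, contents, 8, np.random.default_rng(0), cmap.inner_id
        )
        assert not shortfall
        for b in bins:
            assert cmap.cluster_id[b] == cmap.inner_id
            assert len(contents.solvent_in(b)) >= 1

    def test_solvent_only_bins_preferred(self, make_point_system):
        """3 pure bins + mixed bins, n=5: all pure bins must be chosen."""
        # 1D corridor of bins along x in a 13 nm box; membrane plane seals nothing,
        # single compartment is fine for selection logic
        edge = 1.3
        waters, ions = [], []
        for i in range(10):  # water in bins 0..9
            waters.append([(i + 0.5) * edge, 0.65, 0.65])
        for i in range(3, 10):  # ions in bins 3..9 -> bins 0,1,2 are solvent-only
            ions.append([(i + 0.5) * edge, 0.65, 0.2])
        mem = [[0.65, 6.0, 6.0]]
        pos = mem + waters + ions
        sys_ = make_point_system(
            pos, (13, 13, 13), membrane=[0], solvent=range(1, 11)
        )
        grid = op.make_grid(sys_.box, edge)
        cmap = cluster_solvent(op.label_bins(sys_, grid))
        contents = bin_contents(sys_, grid)
        bins, shortfall = select_source_bins(cmap, contents, 5, np.random.default_rng(2), 0)
        assert not shortfall
        pure = {(i, 0, 0) for i in range(3)}
        assert pure <= set(bins)
        assert len(bins) == 5

    def test_shortfall_flagged(self, make_point_system):
        sys_ = make_point_system(
            [[0.65, 6, 6]] + [[(i + 0.5) * 1.3, 0.65, 0.65] for i in range(4)],
            (13, 13, 13),
            membrane=[0],
            solvent=range(1, 5),
        )
        grid = op.make_grid(sys_.box, 1.3)
        cmap = cluster_solvent(op.label_bins(sys_, grid))
        contents = bin_contents(sys_, grid)
        bins, shortfall = select_source_bins(cmap, contents, 10, np.random.default_rng(0), 0)
        assert shortfall
        assert len(bins) == 4

    def test_no_solvent_terminates_pumping(self, make_point_system):
        sys_ = make_point_system([[0.65, 6, 6]], (13, 13, 13), membrane=[0])
        grid = op.make_grid(sys_.box, 1.3)
        cmap = cluster_solvent(op.label_bins(sys_, grid))
        contents = bin_contents(sys_, grid)
        with pytest.raises(SolventExhaustedError):
            select_source_bins(cmap, contents, 1, np.random.default_rng(0), 0)


class TestFindMolecules:
    def test_single_resident_returned(self, shell_scene):
        sys_, grid, cmap, contents = shell_scene
        flat = contents.solvent_flat_bins
        unique, counts = np.unique(flat, return_counts=True)
        lone_bin = tuple(grid.unflatten(int(unique[counts == 1][0])))
        (mol,) = find_molecules_in_bins(sys_, grid, [lone_bin], np.random.default_rng(0))
        assert mol == int(contents.solvent_in(lone_bin)[0])

    def test_reproducible_choice(self, shell_scene):
        sys_, grid, cmap, contents = shell_scene
        bins, _ = select_source_bins(cmap, contents, 5, np.random.default_rng(3), cmap.inner_id)
        a = find_molecules_in_bins(sys_, grid, bins, np.random.default_rng(9), contents)
        b = find_molecules_in_bins(sys_, grid, bins, np.random.default_rng(9), contents)
        assert a == b

    def test_round_trip_rebinning(self, shell_scene):
        """A chosen molecule's reference site re-bins to its source bin."""
        sys_, grid, cmap, contents = shell_scene
        bins, _ = select_source_bins(cmap, contents, 10, np.random.default_rng(4), cmap.inner_id)
        mols = find_molecules_in_bins(sys_, grid, bins, np.random.default_rng(4), contents)
        for b, mol in zip(bins, mols):
            ref = sys_.molecules[mol][0]
            assert tuple(op.bin_index(sys_.positions[ref], grid)) == b

    def test_empty_bin_is_contract_violation(self, shell_scene):
        sys_, grid, _, contents = shell_scene
        empty = tuple(grid.unflatten(int(np.flatnonzero(contents.solvent_count == 0)[0])))
        with pytest.raises(StateError):
            find_molecules_in_bins(sys_, grid, [empty], np.random.default_rng(0), contents)


class TestChooseTargetBin:
    def test_target_in_compartment_and_reproducible(self, shell_scene):
        _, _, cmap, contents = shell_scene
        a = choose_target_bin(cmap, contents, np.random.default_rng(1), cmap.outer_id)
        b = choose_target_bin(cmap, contents, np.random.default_rng(1), cmap.outer_id)
        assert a == b
        assert cmap.cluster_id[a] == cmap.outer_id

    def test_minimum_solute_fallback(self, make_point_system):
        """With no solute-free bins, only minimum-solute bins are eligible."""
        edge = 1.3
        # 5-bin corridor: membrane seals bin 4; ions in bins 0..3 with
        # counts 2,2,3,4, so the minimum-solute set is bins {0, 1}
        ions = []
        for i, c in enumerate([2, 2, 3, 4]):
            for j in range(c):
                ions.append([(i + 0.5) * edge, 0.3 + 0.1 * j, 0.65])
        mem = [[4.5 * edge, 0.65, 0.65]]
        sys_ = make_point_system(mem + ions, (6.5, 1.3, 1.3), membrane=[0])
        grid = op.make_grid(sys_.box, edge)
        cmap = cluster_solvent(op.label_bins(sys_, grid))
        contents = bin_contents(sys_, grid)
        assert cmap.n_clusters == 1
        hits = {
            choose_target_bin(cmap, contents, np.random.default_rng(s), 0)
            for s in range(30)
        }
        assert hits == {(0, 0, 0), (1, 0, 0)}

    def test_empty_compartment_rejected(self, shell_scene):
        _, _, cmap, contents = shell_scene
        with pytest.raises(StateError):
            choose_target_bin(cmap, contents, np.random.default_rng(0), 99)


class TestInsertionPoint:
    def setup_method(self):
        self.grid = op.make_grid(op.BoxVec(13, 13, 13), 1.3)

    def test_empty_bin_infinite_clearance(self):
        point, clearance = insertion_point(
            self.grid, (2, 2, 2), np.empty((0, 3)), rng=np.random.default_rng(0)
        )
        assert clearance == np.inf
        lo = self.grid.bin_lower_corner((2, 2, 2))
        assert (point >= lo + 0.3).all() and (point <= lo + 1.3 - 0.3).all()

    def test_single_corner_particle_vs_dense_grid_oracle(self, insertion_oracle):
        corner_particle = self.grid.bin_lower_corner((2, 2, 2))[None, :]
        rng = np.random.default_rng(0)
        point, clearance = insertion_point(
            self.grid, (2, 2, 2), corner_particle, n_trials=4000, rng=rng
        )
        opt_point, opt_clear = insertion_oracle(self.grid, (2, 2, 2), corner_particle, 0.3)
        # the optimum is the diagonally opposite margin corner
        assert np.allclose(opt_point, self.grid.bin_lower_corner((2, 2, 2)) + 1.0, atol=0.05)
        assert clearance <= opt_clear + 1e-9
        assert clearance >= opt_clear - 0.08  # within a fine-grid step of optimal

    def test_two_opposite_faces_optimum_near_center(self, insertion_oracle):
        lo = self.grid.bin_lower_corner((1, 1, 1))
        particles = np.array([lo + [0.0, 0.65, 0.65], lo + [1.3, 0.65, 0.65]])
        point, clearance = insertion_point(
            self.grid, (1, 1, 1), particles, n_trials=4000, rng=np.random.default_rng(1)
        )
        opt_point, opt_clear = insertion_oracle(self.grid, (1, 1, 1), particles, 0.3)
        assert abs(clearance - opt_clear) < 0.05
        # the axis joining the two particles must be centered; the other two
        # axes run to the margin to gain distance from both particles at once
        assert abs(point[0] - (lo[0] + 0.65)) < 0.1
        assert abs(opt_point[0] - (lo[0] + 0.65)) < 0.05

    def test_clearance_is_recomputable(self):
        rng = np.random.default_rng(5)
        nearby = rng.uniform(0, 13, size=(40, 3))
        point, clearance = insertion_point(self.grid, (4, 4, 4), nearby, rng=rng)
        d = min_image_distances(point[None, :], nearby, self.grid.box.as_array())[0]
        assert clearance == pytest.approx(d, abs=1e-12)

    def test_clearance_grows_with_trials_in_expectation(self):
        rng = np.random.default_rng(8)
        nearby = rng.uniform(0, 1.3, size=(5, 3)) + self.grid.bin_lower_corner((3, 3, 3))
        def mean_clearance(trials, reps=40):
            vals = [
                insertion_point(
                    self.grid, (3, 3, 3), nearby, n_trials=trials,
                    rng=np.random.default_rng(100 + r),
                )[1]
                for r in range(reps)
            ]
            return np.mean(vals)
        assert mean_clearance(50) > mean_clearance(1)

    def test_margin_validation(self):
        with pytest.raises(ParameterError):
            insertion_point(self.grid, (0, 0, 0), np.empty((0, 3)), margin=0.7)
        with pytest.raises(ParameterError):
            insertion_point(self.grid, (0, 0, 0), np.empty((0, 3)), n_trials=0)

    def test_min_image_used_across_boundary(self):
        """A particle just across the periodic face limits the clearance."""
        other = np.array([[12.99, 0.65, 0.65]])  # adjacent to bin (0,0,0) via PBC
        point, clearance = insertion_point(
            self.grid, (0, 0, 0), other, n_trials=500, rng=np.random.default_rng(2)
        )
        direct = np.linalg.norm(point - other[0])
        assert clearance < direct  # wrapped distance is the shorter one


class TestApplyRelocation:
    def _three_site_system(self):
        # two 3-site waters: resid runs of 3
        pos = np.array(
            [
                [1.0, 1.0, 1.0], [1.1, 1.0, 1.0], [1.0, 1.1, 1.0],
                [5.0, 5.0, 5.0], [5.1, 5.0, 5.0], [5.0, 5.1, 5.0],
            ]
        )
        resids = np.array([1, 1, 1, 2, 2, 2])
        vel = np.full((6, 3), 0.25)
        return ParticleSystem(
            positions=pos,
            velocities=vel,
            names=np.array(["OW", "HW1", "HW2"] * 2),
            resnames=np.array(["SOL"] * 6),
            resids=resids,
            molecules=molecules_from_resids(resids),
            box=op.BoxVec(13, 13, 13),
            groups={"membrane": np.empty(0, dtype=np.int64), "solvent": np.arange(6)},
        )

    def test_empty_plan_is_identity(self, shell_scene):
        sys_, *_ = shell_scene
        out = apply_relocation(sys_, RelocationPlan())
        assert np.array_equal(out.positions, sys_.positions)
        assert np.array_equal(out.velocities, sys_.velocities)

    def test_single_move_changes_three_coordinates(self, shell_scene):
        sys_, grid, cmap, contents = shell_scene
        plan = plan_relocation(
            sys_, grid, cmap, contents, 1, cmap.inner_id, cmap.outer_id,
            np.random.default_rng(0),
        )
        out = apply_relocation(sys_, plan)
        changed = np.flatnonzero((out.positions != sys_.positions).any(axis=1))
        a, z = sys_.molecules[plan.moves[0].molecule]
        assert np.array_equal(changed, np.arange(a, z))
        assert np.array_equal(out.velocities, sys_.velocities)
        assert out.n_particles == sys_.n_particles

    def test_rigid_translation_preserves_geometry_and_velocities(self):
        sys_ = self._three_site_system()
        move = Move(0, (0, 0, 0), (7, 7, 7), np.array([9.8, 9.8, 9.8]), 1.0)
        out = apply_relocation(sys_, RelocationPlan(moves=[move]))
        # reference site lands exactly on the insertion point
        assert np.allclose(out.positions[0], [9.8, 9.8, 9.8])
        d_before = np.linalg.norm(sys_.positions[:3, None] - sys_.positions[None, :3], axis=2)
        d_after = np.linalg.norm(out.positions[:3, None] - out.positions[None, :3], axis=2)
        assert np.allclose(d_before, d_after, atol=1e-12)
        assert np.array_equal(out.velocities, sys_.velocities)
        # the untouched molecule is bit-identical
        assert np.array_equal(out.positions[3:], sys_.positions[3:])

    def test_non_solvent_molecule_rejected(self):
        sys_ = self._three_site_system()
        sys_.groups["solvent"] = np.arange(3, 6)  # first molecule no longer solvent
        move = Move(0, (0, 0, 0), (7, 7, 7), np.array([9.8, 9.8, 9.8]), 1.0)
        with pytest.raises(StateError):
            apply_relocation(sys_, RelocationPlan(moves=[move]))


class TestPlanProperties:
    def test_plan_conserves_inventory_and_is_deterministic(self, shell_scene):
        sys_, grid, cmap, contents = shell_scene
        mk = lambda seed: plan_relocation(
            sys_, grid, cmap, contents, 10, cmap.inner_id, cmap.outer_id,
            np.random.default_rng(seed),
        )
        p1, p2 = mk(7), mk(7)
        assert [(m.molecule, m.source_bin, m.target_bin) for m in p1.moves] == [
            (m.molecule, m.source_bin, m.target_bin) for m in p2.moves
        ]
        assert all(np.array_equal(a.point, b.point) for a, b in zip(p1.moves, p2.moves))
        out = apply_relocation(sys_, p1)
        assert out.n_particles == sys_.n_particles
        assert out.n_molecules == sys_.n_molecules
        assert np.array_equal(out.names, sys_.names)

    def test_static_enclosed_count_drops_by_k(self, shell_scene):
        """Without engine motion, k outward moves lower the inner count by k."""
        from osmopump.compartments import count_enclosed_solvent

        sys_, grid, cmap, contents = shell_scene
        before = count_enclosed_solvent(cmap, contents)
        plan = plan_relocation(
            sys_, grid, cmap, contents, 7, cmap.inner_id, cmap.outer_id,
            np.random.default_rng(3),
        )
        out = apply_relocation(sys_, plan)
        after = count_enclosed_solvent(cmap, bin_contents(out, grid))
        assert before - after == 7

    def test_insertion_points_respect_margin(self, shell_scene):
        sys_, grid, cmap, contents = shell_scene
        plan = plan_relocation(
            sys_, grid, cmap, contents, 15, cmap.inner_id, cmap.outer_id,
            np.random.default_rng(11),
        )
        for mv in plan.moves:
            lo = grid.bin_lower_corner(mv.target_bin)
            assert (mv.point >= lo + 0.3 - 1e-12).all()
            assert (mv.point <= lo + grid.edges - 0.3 + 1e-12).all()

    def test_clearance_matches_independent_recount(self, vesicle):
        """Reported clearance == brute-force min-image NN distance.

        Uses the solvated vesicle so every target bin has populated
        neighbours: the true nearest neighbour then lies within the
        27-bin neighbourhood the clearance is defined over, and a brute
        force over *all* particles must reproduce it exactly.
        """
        grid = op.make_grid(vesicle.box, 1.3)
        cmap = assign_roles(cluster_solvent(op.label_bins(vesicle, grid)), grid)
        contents = bin_contents(vesicle, grid)
        plan = plan_relocation(
            vesicle, grid, cmap, contents, 10, cmap.inner_id, cmap.outer_id,
            np.random.default_rng(13),
        )
        box = vesicle.box.as_array()
        for mv in plan.moves:
            a, z = vesicle.molecules[mv.molecule]
            others = np.delete(vesicle.positions, np.arange(a, z), axis=0)
            d = min_image_distances(mv.point[None, :], others, box)[0]
            assert mv.clearance == pytest.approx(d, abs=1e-9)
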