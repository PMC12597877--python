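"""Walk-engine physics: determinism, unbiasedness, defect monotonicity."""

import numpy as np
import pytest
from scipy import stats

import chemosim as cs
from chemosim.engine import RunSettings, simulate_endpoints
from chemosim.reference import simulate_control_fronts


def _short(seed=0, duration=600.0):
    return RunSettings(duration_virtual_s=duration, dt_s=10.0, seed=seed)


class TestRunSettings:
    @pytest.mark.parametrize("acc", [1, 60, 300])
    def test_valid_accelerations(self, acc):
        assert RunSettings(acceleration=acc).acceleration == acc

    @pytest.mark.parametrize("acc", [0, 2, 100, -1])
    def test_invalid_acceleration_rejected(self, acc):
        with pytest.raises(ValueError):
            RunSettings(acceleration=acc)

    def test_duration_must_divide_by_dt(self):
        with pytest.raises(ValueError):
            RunSettings(duration_virtual_s=7205.0, dt_s=10.0)

    def test_acceleration_changes_wall_clock_only(self):
        slow = RunSettings(acceleration=1)
        fast = RunSettings(acceleration=300)
        assert slow.wall_clock_s == 300 * fast.wall_clock_s
        assert slow.n_steps == fast.n_steps


class TestRun:
    def test_zero_duration_is_identity(self, control_layout):
        plate = cs.load_plate(control_layout, 50, seed=3)
        end, traj = cs.run(plate, _short(duration=0.0))
        np.testing.assert_array_equal(end.positions, plate.positions)
        assert traj.positions.shape == (50, 1, 2)

    def test_agent_count_conserved(self, control_layout):
        plate = cs.load_plate(control_layout, 77, seed=3)
        end, _ = cs.run(plate, _short(seed=5), record_trajectories=False)
        assert end.n_agents == 77

    def test_seeded_determinism(self, control_layout):
        plate = cs.load_plate(control_layout, 60, seed=3)
        a, _ = cs.run(plate, _short(seed=11), record_trajectories=False)
        b, _ = cs.run(plate, _short(seed=11), record_trajectories=False)
        np.testing.assert_array_equal(a.positions, b.positions)

    @pytest.mark.parametrize("acc", [1, 300])
    def test_acceleration_invariance_short_run(self, control_layout, acc):
        plate = cs.load_plate(control_layout, 60, seed=3)
        base, _ = cs.run(
            plate, RunSettings(duration_virtual_s=600, acceleration=60, seed=11),
            record_trajectories=False,
        )
        other, _ = cs.run(
            plate, RunSettings(duration_virtual_s=600, acceleration=acc, seed=11),
            record_trajectories=False,
        )
        np.testing.assert_array_equal(base.positions, other.positions)

    def test_virtual_time_advances_to_duration(self, control_layout):
        plate = cs.load_plate(control_layout, 20, seed=1)
        end, _ = cs.run(plate, _short(seed=2), record_trajectories=False)
        assert end.virtual_time_s == 600.0

    def test_unloaded_plate_rejected(self):
        with pytest.raises(cs.StateError):
            cs.run(None, _short())

    def test_trajectories_start_in_central_well(self, control_layout):
        plate = cs.load_plate(control_layout, 30, seed=2)
        _, traj = cs.run(plate, _short(seed=4))
        r0 = np.hypot(traj.positions[:, 0, 0], traj.positions[:, 0, 1])
        assert np.all(r0 <= control_layout.well_radius_mm)
        assert traj.positions.shape[1] == 61

    def test_zero_speed_multiplier_freezes_positions(self):
        frozen = cs.SampleProfile(
            "stuck", "patient", random_motility_multiplier=0.0
        )
        layout = cs.WellLayout(
            cs.get_reagent("diluent"), cs.get_reagent("fMLP"), frozen
        )
        plate = cs.load_plate(layout, 40, seed=6)
        end, _ = cs.run(plate, _short(seed=7), record_trajectories=False)
        np.testing.assert_array_equal(end.positions, plate.positions)


class TestStep:
    def test_step_advances_clock_and_conserves_agents(self, control_layout):
        plate = cs.load_plate(control_layout, 25, seed=1)
        rng = np.random.default_rng(0)
        nxt = cs.step(plate, 10.0, rng)
        assert nxt.virtual_time_s == 10.0
        assert nxt.n_agents == 25
        assert plate.virtual_time_s == 0.0  # original untouched

    def test_step_displacement_bounded_by_speed_cap(self, control_layout):
        plate = cs.load_plate(control_layout, 25, seed=1)
        nxt = cs.step(plate, 10.0, np.random.default_rng(0))
        moved = np.linalg.norm(nxt.positions - plate.positions, axis=1)
        cap_mm = 2.0 * plate.layout.center_sample.motility * 10.0 / 60000.0
        assert np.all(moved <= cap_mm + 1e-12)


class TestWalkStatistics:
    def test_unbiased_walk_has_zero_mean_axial_displacement(self, diluent_layout):
        """κ = 0 everywhere: axial drift must vanish (|mean| < 3 SE)."""
        plate = cs.load_plate(diluent_layout, 10_000, seed=12)
        end, _ = cs.run(plate, RunSettings(seed=13), record_trajectories=False)
        dx = end.positions[:, 0] - plate.positions[:, 0]
        se = dx.std(ddof=1) / np.sqrt(dx.size)
        assert abs(dx.mean()) < 3.0 * se

    def test_defect_monotonicity(self):
        """Stronger fMLP defects never increase the mean directed front."""
        fronts = {}
        for s in (0.3, 0.6):
            patient = cs.make_sample("patient", {"fMLP": s}, label=f"s{s}")
            f = simulate_control_fronts("fMLP", 50, seed=77, control=patient)
            fronts[s] = f[:, 1].mean()
        assert fronts[0.6] >= fronts[0.3]

    def test_directed_exceeds_random_for_control(self, anchor_fronts):
        """Chemoattracted fronts beat diluent-side fronts (paired, p < 0.01)."""
        rand, direct = anchor_fronts[:, 0], anchor_fronts[:, 1]
        res = stats.ttest_rel(direct, rand, alternative="greater")
        assert res.pvalue < 0.01

    def test_diffusive_limit_msd_linear(self):
        """persistence = 0, κ = 0: mean squared displacement grows linearly."""
        wanderer = cs.SampleProfile("iso", "patient", persistence=0.0)
        layout = cs.WellLayout(
            cs.get_reagent("diluent"), cs.get_reagent("diluent"), wanderer
        )
        plate = cs.load_plate(layout, 2000, seed=21)
        _, traj = cs.run(plate, RunSettings(seed=22))
        disp = traj.positions - traj.positions[:, :1, :]
        msd = (disp**2).sum(axis=2).mean(axis=0)
        t = traj.times_s
        slope, intercept, r, *_ = stats.linregress(t[1:], msd[1:])
        assert r**2 > 0.99


class TestBatchedEndpoints:
    def test_batch_matches_individual_runs(self, control_layout):
        tasks = [(control_layout, 100 + i, 200 + i) for i in range(3)]
        batch = simulate_endpoints(tasks, _short(seed=0), n_cells=40)
        for i, (layout, ps, rs) in enumerate(tasks):
            plate = cs.load_plate(layout, 40, seed=ps)
            end, _ = cs.run(plate, _short(seed=rs), record_trajectories=False)
            np.testing.assert_array_equal(batch[i], end.positions)

    def test_mixed_geometry_rejected(self, control_layout):
        other = cs.WellLayout(
            cs.get_reagent("diluent"),
            cs.get_reagent("fMLP"),
            cs.make_sample("control"),
            well_spacing_mm=6.0,
        )
        with pytest.raises(ValueError, match="geometry"):
            simulate_endpoints(
                [(control_layout, 1, 2), (other, 3, 4)], _short(), n_cells=10
            )
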