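"""Graticule arithmetic, leading-front extraction and chemotaxis metrics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import chemosim as cs
from chemosim.engine import RunSettings, TrajectorySet
from chemosim.graticule import GridSpec, Measurement, _front_from_axial


def _make_state(x_positions, radius=1.2):
    """A synthetic end state with agents at given axial positions (y = 0)."""
    layout = cs.WellLayout(
        cs.get_reagent("diluent"), cs.get_reagent("fMLP"), cs.make_sample("control"),
        well_radius_mm=radius,
    )
    x = np.asarray(x_positions, dtype=float)
    return cs.PlateState(
        layout=layout,
        positions=np.column_stack([x, np.zeros_like(x)]),
        headings=np.zeros_like(x),
        speeds=np.zeros_like(x),
        virtual_time_s=7200.0,
        seed=0,
    )


def _make_traj(start_x, end_x, dt=10.0, radius=1.2):
    start = np.asarray(start_x, float)
    end = np.asarray(end_x, float)
    pos = np.zeros((len(start), 2, 2))
    pos[:, 0, 0] = start
    pos[:, 1, 0] = end
    return TrajectorySet(
        times_s=np.array([0.0, dt]),
        positions=pos,
        sample_label="fixture",
        left_reagent="diluent",
        right_reagent="fMLP",
        settings=RunSettings(duration_virtual_s=dt, dt_s=dt),
        well_radius_mm=radius,
    )


class TestGridArithmetic:
    def test_worked_example_five_and_a_half_grids(self):
        assert cs.grids_to_mm(5.5, 0.8) == pytest.approx(0.44, rel=1e-12)

    def test_zero_reading(self):
        assert cs.grids_to_mm(0, 0.8) == 0.0

    def test_full_field_width(self):
        assert cs.grids_to_mm(10, 0.8) == pytest.approx(0.8, rel=1e-12)

    def test_mm_per_unit_at_measurement_zoom(self):
        assert GridSpec().mm_per_unit == pytest.approx(0.08, rel=1e-12)

    def test_negative_reading_rejected(self):
        with pytest.raises(ValueError):
            cs.grids_to_mm(-1.0, 0.8)

    def test_measurement_total(self):
        m = Measurement(grids=2.5, anchor_offsets_mm=(0.8, 0.8), field_width_mm=0.8)
        assert m.total_mm == pytest.approx(1.8, rel=1e-12)


class TestChainedMeasure:
    def test_no_anchors_reduces_to_grid_reading(self):
        assert cs.chained_measure([], 5.5, 0.8) == pytest.approx(0.44, rel=1e-12)

    def test_single_full_grid_relocation(self):
        assert cs.chained_measure([0.8], 0, 0.8) == pytest.approx(0.8, rel=1e-12)

    def test_two_relocations_plus_residual(self):
        assert cs.chained_measure([0.8, 0.8], 2.5, 0.8) == pytest.approx(1.8, rel=1e-12)

    @given(
        d=st.floats(0.0, 5.0),
        cuts=st.lists(st.floats(0.01, 0.99), max_size=4),
        width=st.floats(0.1, 2.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_any_partition_recovers_total_exactly(self, d, cuts, width):
        """Splitting a distance into anchor hops + residual changes nothing."""
        bounds = sorted(c * d for c in cuts)
        offsets = np.diff([0.0] + bounds).tolist()
        residual = d - sum(offsets)
        grids = residual / (width / 10.0)
        assert cs.chained_measure(offsets, grids, width) == pytest.approx(
            d, abs=1e-9
        )

    @given(d=st.floats(0.0, 2.0), width=st.floats(0.2, 2.0))
    @settings(max_examples=100, deadline=None)
    def test_zoom_invariance_of_quantized_readings(self, d, width):
        """A half-unit-quantized reading at any zoom recovers d within w/20."""
        grids = round(d / (width / 10.0) * 2.0) / 2.0
        assert abs(cs.grids_to_mm(grids, width) - d) <= width / 20.0 + 1e-12


class TestLeadingFront:
    def test_no_migration_gives_zero(self):
        state = _make_state(np.zeros(100))
        assert cs.leading_front(state, "right") == 0.0

    def test_uniform_band_at_anchor_distance(self):
        state = _make_state(np.full(50, 1.2 + 0.44))
        assert cs.leading_front(state, "right") == pytest.approx(0.44)

    def test_matches_empirical_percentile_on_ladder(self):
        x = 1.2 + 0.001 * np.arange(1, 1001)
        state = _make_state(x)
        assert cs.leading_front(state, "right") == pytest.approx(0.95)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_agrees_with_brute_force_sort(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(0.5, 0.8, size=500)
        disp = x - 1.2
        moved = np.sort(disp[disp > 0])
        expected = moved[math.ceil(0.95 * moved.size) - 1] if moved.size else 0.0
        assert _front_from_axial(x, "right", 1.2) == pytest.approx(expected)

    def test_left_side_uses_mirrored_axis(self):
        state = _make_state(-np.full(10, 1.2 + 0.3))
        assert cs.leading_front(state, "left") == pytest.approx(0.3)
        assert cs.leading_front(state, "right") == 0.0

    def test_empty_plate_rejected(self):
        state = _make_state(np.zeros(1))
        state.positions = state.positions[:0]
        with pytest.raises(ValueError):
            cs.leading_front(state, "right")


class TestChemotaxisMetrics:
    def test_stationary_population(self):
        traj = _make_traj([0, 0, 0], [0, 0, 0])
        m = cs.chemotaxis_metrics(traj, "right")
        assert m["distance_mm"] == 0.0
        assert m["cell_ratio"] == 0.0
        assert math.isnan(m["index"])

    def test_index_ratio_on_split_population(self):
        """Half the cells 0.44 mm past the right edge, half 0.22 past the left."""
        start = [0.0] * 10
        end = [1.2 + 0.44] * 5 + [-(1.2 + 0.22)] * 5
        m = cs.chemotaxis_metrics(_make_traj(start, end), "right")
        assert m["distance_mm"] == pytest.approx(0.44)
        assert m["index"] == pytest.approx(2.0)

    def test_max_speed_unit_conversion(self):
        """One 2 μm step in a 10 s interval is 12 μm/min."""
        traj = _make_traj([0.0], [0.002], dt=10.0)
        m = cs.chemotaxis_metrics(traj, "right")
        assert m["max_speed_um_min"] == pytest.approx(12.0)

    def test_cell_ratio_counts_net_axial_movers(self):
        start = [0.0, 0.0, 0.0, 0.0]
        end = [0.25, 0.15, 0.05, -0.5]  # two beyond the 0.1 mm threshold
        m = cs.chemotaxis_metrics(_make_traj(start, end), "right")
        assert m["cell_ratio"] == pytest.approx(0.5)

    def test_measure_run_reports_both_sides(self):
        state = _make_state([1.2 + 0.4] * 20 + [-(1.2 + 0.1)] * 20)
        result = cs.measure_run(state)
        assert result.directed_mm == pytest.approx(0.4)
        assert result.random_mm == pytest.approx(0.1)
        assert result.reagent == "fMLP"
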