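"""Sectors, neighbourhoods, trigger assignment and wave labelling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import shimmerwave as sw
from shimmerwave.neighborhood import (
    assign_all_triggers,
    sector_of_angle,
    sector_offset,
    opposite_sector,
)


class TestSectorOf:
    @pytest.mark.parametrize(
        "dxy,expected",
        [
            ((10, 0), 1),     # from Right
            ((0, 10), 3),     # from Bottom (image y points down)
            ((-10, 0), 5),    # from Left
            ((0, -10), 7),    # from Top
            ((10, 10), 2),    # from Bottom-right
        ],
    )
    def test_cardinal_and_diagonal_sectors(self, dxy, expected):
        assert sw.sector_of((0, 0), dxy) == expected

    def test_boundary_angle_belongs_to_next_sector(self):
        assert sector_of_angle(22.5) == 2
        assert sector_of_angle(337.5) == 1
        assert sector_of_angle(67.5) == 3

    def test_coincident_positions_rejected(self):
        with pytest.raises(ValueError):
            sw.sector_of((1.0, 1.0), (1.0, 1.0))

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(angle=st.floats(0, 359.999), k=st.integers(0, 7))
    def test_rotation_by_45_degrees_shifts_sector_cyclically(self, angle, k):
        s0 = sector_of_angle(angle)
        s1 = sector_of_angle(angle + 45.0 * k)
        assert s1 == (s0 - 1 + k) % 8 + 1

    def test_opposite_sector(self):
        assert [opposite_sector(s) for s in range(1, 9)] == [5, 6, 7, 8, 1, 2, 3, 4]

    def test_sector_offset_range(self):
        offs = {sector_offset(s, 3) for s in range(1, 9)}
        assert offs == {-3, -2, -1, 0, 1, 2, 3, 4}


class TestNeighbors:
    def test_strict_radius_excludes_boundary(self):
        table = pd.DataFrame(
            {
                "agent_id": [0, 1, 2],
                "x_mm": [0.0, 40.0, 39.99],
                "y_mm": [0.0, 0.0, 0.0],
            }
        )
        ids = sw.neighbors(table, 0, 40.0)
        assert list(ids) == [2]

    def test_matches_brute_force_scan(self, lattice600):
        t = lattice600.table
        rng = np.random.default_rng(0)
        for aid in rng.choice(t.agent_id.to_numpy(), 5, replace=False):
            got = set(sw.neighbors(t, aid, 40.0))
            fx, fy = t.set_index("agent_id").loc[aid, ["x_mm", "y_mm"]]
            expected = {
                int(r.agent_id)
                for r in t.itertuples()
                if r.agent_id != aid and np.hypot(r.x_mm - fx, r.y_mm - fy) < 40.0
            }
            assert got == expected

    def test_interior_near_count_matches_field_occupancy(self, lattice600):
        t = lattice600.table
        mid = ((t.x_mm - 320) ** 2 + (t.y_mm - 320) ** 2).idxmin()
        n = len(sw.neighbors(t, int(t.loc[mid, "agent_id"]), 40.0))
        assert 4 <= n <= 7


class TestAssignTrigger:
    def _incident(self, agent, t0, wave=0):
        return pd.Series({"agent_id": agent, "t0": t0, "wave_id": wave})

    def test_no_candidate_within_window_is_untriggered(self, agents_line):
        focus = self._incident(2, 100)
        cands = pd.DataFrame(
            {"agent_id": [1], "t0": [90], "wave_id": [0]}  # 10 frames: too old
        )
        trig, sec = sw.assign_trigger(focus, cands, agents_line.table)
        assert trig is None and sec is None

    def test_closest_candidate_wins(self):
        table = pd.DataFrame(
            {
                "agent_id": [0, 1, 2],
                "x_mm": [50.0, 70.0, 85.0],   # 20 mm and 35 mm away
                "y_mm": [50.0, 50.0, 50.0],
            }
        )
        focus = self._incident(0, 100)
        cands = pd.DataFrame(
            {"agent_id": [1, 2], "t0": [97, 96], "wave_id": [0, 0]}
        )
        trig, sec = sw.assign_trigger(focus, cands, table)
        assert trig == 1
        assert sec == 1  # from the right

    def test_tie_breaks_on_earlier_t0_then_lower_id(self):
        table = pd.DataFrame(
            {
                "agent_id": [0, 1, 2],
                "x_mm": [50.0, 70.0, 30.0],   # both at 20 mm
                "y_mm": [50.0, 50.0, 50.0],
            }
        )
        focus = self._incident(0, 100)
        cands = pd.DataFrame(
            {"agent_id": [1, 2], "t0": [98, 97], "wave_id": [0, 0]}
        )
        trig, _ = sw.assign_trigger(focus, cands, table)
        assert trig == 2  # earlier onset wins the distance tie

    def test_assignment_is_row_order_invariant(self, lattice600, directed_sim):
        strengths, truth = directed_sim
        inc = truth.to_incidents()[["agent_id", "t0", "wave_id", "peak_rel"]]
        a = assign_all_triggers(inc, lattice600.table)
        b = assign_all_triggers(
            inc.sample(frac=1.0, random_state=7), lattice600.table
        ).sort_index()
        pd.testing.assert_frame_equal(a, b)

    def test_recovers_simulation_edges(self, clean_fitted, clean_sim):
        _, truth = clean_sim
        fb = clean_fitted.incidents.query("role == 'focus'")
        assigned = set(
            zip(fb.trigger_id.astype(int), fb.agent_id.astype(int))
        )
        true_edges = set(zip(truth.edges.src, truth.edges.dst))
        recovered = len(assigned & true_edges) / len(true_edges)
        assert recovered >= 0.95


class TestWaveDirection:
    @pytest.mark.parametrize("dir_true", [1, 2, 3, 4])
    def test_recovers_all_key_directions(self, lattice_small, dir_true):
        params = sw.WaveParams(dir_true=dir_true, noise_sd=0.0, seed=5)
        strengths, truth = sw.simulate_wave(lattice_small, params)
        inc = truth.to_incidents()
        assert sw.classify_wave_direction(inc, lattice_small.table) == dir_true

    def test_simultaneous_onsets_are_flagged_undefined(self, lattice_small):
        inc = pd.DataFrame(
            {"agent_id": lattice_small.ids, "t0": 10}
        )
        assert sw.classify_wave_direction(inc, lattice_small.table) is None

    def test_too_few_incidents_undefined(self, lattice_small):
        inc = pd.DataFrame({"agent_id": lattice_small.ids[:5], "t0": range(5)})
        assert sw.classify_wave_direction(inc, lattice_small.table) is None

    def test_manual_override_wins(self, lattice_small):
        inc = pd.DataFrame({"agent_id": lattice_small.ids, "t0": 10})
        assert sw.classify_wave_direction(inc, lattice_small.table, override=2) == 2


class TestGroupWaves:
    def test_gap_splits_waves(self):
        inc = pd.DataFrame({"agent_id": [1, 2, 3, 4], "t0": [0, 10, 100, 105]})
        out = sw.group_waves(inc, gap_frames=48)
        assert out.wave_id.tolist() == [0, 0, 1, 1]

    def test_empty_table_is_valid(self):
        out = sw.group_waves(pd.DataFrame(columns=["agent_id", "t0"]), 48)
        assert "wave_id" in out.columns and out.empty
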