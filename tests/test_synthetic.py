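"""Lattice construction, wave simulation and frame rendering."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import shimmerwave as sw
from tests.conftest import line_agents


def brute_force_neighbor_count(table, agent_id, radius):
    t = table.set_index("agent_id")
    fx, fy = t.loc[agent_id, ["x_mm", "y_mm"]]
    n = 0
    for other, row in t.iterrows():
        if other == agent_id:
            continue
        if np.hypot(row.x_mm - fx, row.y_mm - fy) < radius:
            n += 1
    return n


def interior_ids(agents, margin=100.0):
    t = agents.table
    return t[
        (t.x_mm > t.x_mm.min() + margin)
        & (t.x_mm < t.x_mm.max() - margin)
        & (t.y_mm > t.y_mm.min() + margin)
        & (t.y_mm < t.y_mm.max() - margin)
    ]["agent_id"].to_numpy()


class TestBuildLattice:
    def test_degenerate_extent_gives_single_agent(self):
        with pytest.warns(UserWarning):
            agents = sw.build_lattice((60, 60), 100.0, jitter_sd=0.0)
        assert len(agents) == 1

    def test_interior_near_neighbourhood_occupancy(self):
        agents = sw.build_lattice((600, 600), 29.0, jitter_sd=0.0)
        for aid in interior_ids(agents)[:10]:
            assert brute_force_neighbor_count(agents.table, aid, 40.0) == 6

    def test_far_neighbourhood_occupancy(self):
        agents = sw.build_lattice((600, 600), 29.0, jitter_sd=0.0)
        counts = [
            brute_force_neighbor_count(agents.table, aid, 100.0)
            for aid in interior_ids(agents)[:10]
        ]
        assert all(20 <= c <= 45 for c in counts)

    def test_jitter_respects_min_spacing(self):
        agents = sw.build_lattice((400, 400), 29.0, jitter_sd=8.0, seed=5)
        xy = agents.table[["x_mm", "y_mm"]].to_numpy()
        d = np.hypot(xy[:, None, 0] - xy[None, :, 0], xy[:, None, 1] - xy[None, :, 1])
        np.fill_diagonal(d, np.inf)
        assert d.min() >= agents.min_spacing_mm - 1e-9

    def test_px_positions_follow_scale(self):
        agents = sw.build_lattice((200, 200), 29.0, jitter_sd=1.0, seed=2)
        t = agents.table
        assert np.array_equal(
            t.x_px.to_numpy(), np.floor(t.x_mm / 0.30 + 0.5).astype(int)
        )

    def test_duplicate_ids_rejected(self):
        t = line_agents().table.copy()
        t.loc[1, "agent_id"] = 0
        with pytest.raises(ValueError):
            sw.AgentSet(t)


class TestSimulateWave:
    def test_deterministic_chain_on_a_line(self, agents_line):
        params = sw.WaveParams(
            dir_true=3, p_directed=1.0, noise_sd=0.0, amp_sd=0.0, seed=0
        )
        _, truth = sw.simulate_wave(
            agents_line, params, generator_ids=np.array([0])
        )
        edges = truth.edges.sort_values("frame")
        assert list(zip(edges.src, edges.dst)) == [(0, 1), (1, 2), (2, 3), (3, 4)]
        # onsets advance by exactly the latency each hop
        assert np.diff(edges.frame.to_numpy()).tolist() == [3, 3, 3]

    def test_identity_coupling_preserves_peaks(self, agents_line):
        params = sw.WaveParams(
            dir_true=3, p_directed=1.0, k_couple=1.0, noise_sd=0.0, seed=1
        )
        _, truth = sw.simulate_wave(agents_line, params, generator_ids=np.array([0]))
        peaks = truth.incidents.set_index("agent_id")["peak_rel"]
        for e in truth.edges.itertuples():
            assert peaks[e.dst] == pytest.approx(peaks[e.src])

    def test_random_attribution_sectors_are_uniform(self, lattice600):
        counts = np.zeros(8)
        n_tot = 0
        for s in range(4):
            params = sw.WaveParams(dir_true=3, p_directed=0.0, seed=50 + s)
            _, truth = sw.simulate_wave(lattice600, params)
            vc = truth.edges.recorded_sector.value_counts()
            for k, v in vc.items():
                counts[k - 1] += v
            n_tot += len(truth.edges)
        assert n_tot >= 1000
        # every sector count within the exact binomial 99% interval
        lo = stats.binom.ppf(0.005, n_tot, 1 / 8)
        hi = stats.binom.ppf(0.995, n_tot, 1 / 8)
        assert counts.min() >= lo and counts.max() <= hi

    def test_trigger_graph_conservation(self, directed_sim):
        _, truth = directed_sim
        n_non_gen = (~truth.incidents.is_generator).sum()
        assert len(truth.edges) == n_non_gen

    def test_refractory_gap_between_repeat_incidents(self, lattice600):
        params = sw.WaveParams(dir_true=3, seed=9)
        _, truth = sw.simulate_wave(
            lattice600, params, n_waves=3,
            drive_interval_frames=params.refractory_frames,
        )
        for _, g in truth.incidents.groupby("agent_id"):
            if len(g) > 1:
                assert np.diff(np.sort(g.t0.to_numpy())).min() >= params.refractory_frames

    def test_seeded_runs_are_bit_reproducible(self, lattice_small):
        params = sw.WaveParams(dir_true=2, p_directed=0.7, seed=11)
        s1, t1 = sw.simulate_wave(lattice_small, params)
        s2, t2 = sw.simulate_wave(lattice_small, params)
        pd.testing.assert_frame_equal(s1, s2)
        pd.testing.assert_frame_equal(t1.edges, t2.edges)

    def test_unreachable_agents_flag_empty_wave(self):
        far_apart = line_agents(n=3, spacing_mm=200.0)
        params = sw.WaveParams(dir_true=3, seed=0)
        with pytest.warns(UserWarning, match="empty wave"):
            _, truth = sw.simulate_wave(
                far_apart, params, generator_ids=np.array([0])
            )
        assert truth.empty

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            sw.WaveParams(p_directed=1.5)
        with pytest.raises(ValueError):
            sw.WaveParams(refractory_ms=100.0, pulse_ms=200.0)
        with pytest.raises(ValueError):
            sw.WaveParams(latency_frames=0)


class TestRenderFrames:
    def test_constant_strengths_render_identically(self, agents_line):
        strengths = pd.DataFrame(
            np.full((4, 5), 1.08), columns=agents_line.ids
        )
        stack = sw.render_frames(
            agents_line, strengths, sw.RenderParams(noise_sd=0.0)
        )
        assert all(np.array_equal(stack[0], f) for f in stack[1:])

    def test_abdomen_glyph_width_is_20px(self):
        assert sw.RenderParams().abdomen_width_px == 20

    def test_step_displacement_changes_only_that_agents_roi(self, agents_line):
        vals = np.full((2, 5), 1.08)
        vals[1, 2] = 4.0
        stack = sw.render_frames(
            agents_line,
            pd.DataFrame(vals, columns=agents_line.ids),
            sw.RenderParams(noise_sd=0.0),
        )
        d = sw.diff_image(stack[0], stack[1])
        ys, xs = np.nonzero(d)
        t = agents_line.table.set_index("agent_id")
        cx, cy = t.loc[2, ["x_px", "y_px"]]
        assert len(ys) > 0
        assert np.all(np.abs(xs - cx) <= 30) and np.all(np.abs(ys - cy) <= 30)

    def test_pulse_duration_covers_12_frames(self):
        assert sw.WaveParams().pulse_frames == 12
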