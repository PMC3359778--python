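"""Linearity and continuity statistics."""

import numpy as np
import pandas as pd
import pytest

import shimmerwave as sw
from shimmerwave.wavestats import (
    continuity_profile,
    estimate_linearity,
    linearity_analysis,
    linearity_histogram,
    test_coincidence as coincidence_test,
)
from shimmerwave.neighborhood import sector_of, sector_offset


def incidents_table(dir_trigs, dir_wav=3, c_ws=3):
    n = len(dir_trigs)
    return pd.DataFrame(
        {
            "agent_id": np.arange(n),
            "t0": np.arange(n),
            "peak_rel": np.full(n, 4.0),
            "c_ws": np.full(n, c_ws),
            "wave_id": np.zeros(n, dtype=int),
            "role": ["focus"] * n,
            "trigger_id": pd.array(np.zeros(n), dtype="Int64"),
            "dir_trig": pd.array(dir_trigs, dtype="Int64"),
            "dir_wav": np.full(n, dir_wav),
        }
    )


class TestLinearityHistogram:
    def test_single_sector_concentration(self):
        rel, counts = linearity_histogram(incidents_table([5] * 20))
        assert rel.loc[3, 5] == 1.0
        assert rel.loc[3].drop(5).eq(0).all()

    def test_uniform_triggers_approach_unity_everywhere(self):
        rng = np.random.default_rng(0)
        sectors = np.repeat(np.arange(1, 9), 200)
        rng.shuffle(sectors)
        rel, _ = linearity_histogram(incidents_table(sectors))
        assert rel.loc[3].min() == 1.0  # exactly equal counts

    def test_max_is_one_per_wave_direction(self, fitted):
        rel = fitted.linearity.rel_n_fb
        assert (rel.max(axis=1) == 1.0).all()

    def test_empty_stratum_warns(self):
        inc = incidents_table([5] * 3)
        inc["c_ws"] = 7  # outside the pooled range 1-6
        with pytest.warns(UserWarning):
            rel, _ = linearity_histogram(inc)
        assert rel.empty


class TestCoincidence:
    def test_uniform_histogram_is_false(self):
        rel = pd.DataFrame(
            [[0.5] * 8], index=pd.Index([3]), columns=range(1, 9)
        )
        assert coincidence_test(rel) == {3: False}

    def test_single_aligned_sector_is_true(self):
        row = [0.0] * 8
        row[5 - 1] = 1.0  # sector 5 = origin of dir_WAV 3
        rel = pd.DataFrame([row], index=pd.Index([3]), columns=range(1, 9))
        assert coincidence_test(rel) == {3: True}

    def test_misaligned_peak_is_false(self):
        row = [0.0] * 8
        row[1 - 1] = 1.0  # opposite side
        rel = pd.DataFrame([row], index=pd.Index([3]), columns=range(1, 9))
        assert coincidence_test(rel) == {3: False}

    @pytest.mark.parametrize("dir_true", [1, 2, 3, 4])
    def test_directed_simulations_coincide(self, lattice600, dir_true):
        params = sw.WaveParams(dir_true=dir_true, p_directed=0.3, seed=20 + dir_true)
        _, truth = sw.simulate_wave(lattice600, params, n_waves=2)
        lin = linearity_analysis(truth.to_incidents())
        assert lin.coincidence[dir_true] is True


class TestEstimateLinearity:
    def test_flat_histogram_has_zero_estimates(self):
        a, b = estimate_linearity([0.4] * 8, poly_min=0.4)
        assert a == 0.0 and b == 0.0

    def test_hand_built_histogram_oracle(self):
        rel = [1.0, 0.5, 0.4, 0.4, 0.4, 0.4, 0.4, 0.4]
        a, b = estimate_linearity(rel, poly_min=0.4)
        expected = (0.6 + 0.1) / 3.9 * 100  # hand computation
        assert a == pytest.approx(expected)
        assert b == pytest.approx(expected)

    def test_estimate_b_never_exceeds_a_when_polymin_below_median(self, fitted):
        lin = fitted.linearity
        for d in lin.estimate_A:
            if lin.poly_min[d] <= lin.median_level[d]:
                assert lin.estimate_B[d] <= lin.estimate_A[d] + 1e-9

    def test_monotone_in_p_directed(self, lattice600):
        """Directedness share B increases with the directed-trigger rate."""
        means = []
        for p in (0.0, 0.5, 1.0):
            vals = []
            for s in range(2):
                params = sw.WaveParams(dir_true=3, p_directed=p, seed=300 + s)
                _, truth = sw.simulate_wave(lattice600, params, n_waves=2)
                vals.append(linearity_analysis(truth.to_incidents()).estimate_B_mean)
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]


class TestContinuityProfile:
    def test_profile_peaks_at_trigger_sector_for_directed_waves(
        self, lattice600, fitted
    ):
        cont = fitted.continuity
        for c_ws, row in cont.rel_n_nh.iterrows():
            assert row.idxmax() == 0

    def test_pure_trigger_sector_activity_gives_full_excess(self):
        # focus at origin triggered from the right; all prior activity there
        agents = pd.DataFrame(
            {
                "agent_id": [0, 1, 2],
                "x_mm": [50.0, 80.0, 85.0],
                "y_mm": [50.0, 50.0, 50.0],
            }
        )
        inc = pd.DataFrame(
            {
                "agent_id": [1, 2, 0],
                "t0": [8, 9, 12],
                "peak_rel": [4.0, 4.0, 4.0],
                "c_ws": [3, 3, 3],
                "wave_id": [0, 0, 0],
                "role": ["untriggered-active", "focus", "focus"],
                "trigger_id": pd.array([None, 1, 1], dtype="Int64"),
                "dir_trig": pd.array([None, 1, 1], dtype="Int64"),
                "dir_wav": [1, 1, 1],
            }
        )
        cont = continuity_profile(inc, agents)
        assert cont.rel_n_nh.loc[3, 0] == 1.0
        assert cont.excess_rate_pooled == pytest.approx(100.0)

    def test_isotropic_activity_is_flat(self):
        # ring of previously active neighbours, one per sector
        rng_ids = np.arange(1, 9)
        angles = np.deg2rad(45.0 * (rng_ids - 1))
        agents = pd.DataFrame(
            {
                "agent_id": np.concatenate([[0], rng_ids]),
                "x_mm": np.concatenate([[0.0], 60 * np.cos(angles)]),
                "y_mm": np.concatenate([[0.0], 60 * np.sin(angles)]),
            }
        )
        inc = pd.DataFrame(
            {
                "agent_id": np.concatenate([rng_ids, [0]]),
                "t0": [5] * 8 + [10],
                "peak_rel": [4.0] * 9,
                "c_ws": [3] * 9,
                "wave_id": [0] * 9,
                "role": ["untriggered-active"] * 8 + ["focus"],
                "trigger_id": pd.array([None] * 8 + [1], dtype="Int64"),
                "dir_trig": pd.array([None] * 8 + [1], dtype="Int64"),
                "dir_wav": [1] * 9,
            }
        )
        cont = continuity_profile(inc, agents)
        assert cont.rel_n_nh.loc[3].eq(1.0).all()
        assert cont.excess_rate_pooled == pytest.approx(0.0)

    def test_counts_match_brute_force_scan(self, lattice_small):
        """Histogram equals an independent triple scan on a small instance."""
        params = sw.WaveParams(dir_true=3, seed=33)
        strengths, truth = sw.simulate_wave(lattice_small, params)
        res = sw.ShimmeringModel.from_simulation(lattice_small, strengths).fit()
        inc = res.incidents
        cont = continuity_profile(inc, lattice_small.table, window_frames=15)

        pos = lattice_small.table.set_index("agent_id")[["x_mm", "y_mm"]]
        brute = {}
        nf = {}
        fb = inc[(inc.role == "focus") & inc.dir_trig.notna() & inc.c_ws.between(1, 5)]
        for f in fb.itertuples():
            nf[f.c_ws] = nf.get(f.c_ws, 0) + 1
            for o in inc.itertuples():
                if o.agent_id == f.agent_id or o.wave_id != f.wave_id:
                    continue
                dt = f.t0 - o.t0
                if not (1 <= dt <= 15):
                    continue
                fx, fy = pos.loc[f.agent_id]
                ox, oy = pos.loc[o.agent_id]
                if np.hypot(ox - fx, oy - fy) >= 100.0:
                    continue
                s = sector_of((fx, fy), (ox, oy))
                off = 45 * sector_offset(s, int(f.dir_trig))
                brute[(f.c_ws, off)] = brute.get((f.c_ws, off), 0) + 1
        for (c, off), n in brute.items():
            assert cont.mean_counts.loc[c, off] * nf[c] == pytest.approx(n)

    def test_linearity_counts_match_brute_force(self, fitted):
        rel, counts = linearity_histogram(fitted.incidents)
        inc = fitted.incidents
        fb = inc[(inc.role == "focus") & inc.dir_trig.notna()
                 & inc.dir_wav.notna() & inc.c_ws.between(1, 6)]
        for d in counts.index:
            for s in range(1, 9):
                expected = ((fb.dir_wav == d) & (fb.dir_trig == s)).sum()
                assert counts.loc[d, s] == expected
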