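"""Agent-based synthetic shimmering waves with known ground truth.

The generator stands in for stereo video of a giant honeybee nest: it
builds a quasi-planar lattice of agents (bees) on the nest surface,
propagates excitable-media waves across it by chain ("bucket bridging")
transfer with a refractory period, and can render the result as 8-bit
grayscale frame stacks so the whole measurement pipeline can be exercised
end to end without field data.

Model in brief
--------------
Agents sit on a jittered hexagonal lattice (z ~ 0). A wave starts at a
generator cohort on the edge the wave comes from. An inactive,
non-refractory agent joins the wave ``latency_frames`` frames after a near
neighbour (distance < 40 mm) joined; its abdomen-flip pulse is a raised
cosine of ~200 ms whose peak excess over the quiescent level couples to
its trigger's peak with coefficient ``k_couple``. After flipping, the
agent is refractory for ~800 ms. With probability ``p_directed`` the
*recorded* trigger attribution is the mechanically triggering (nearest
qualifying) neighbour, otherwise a uniformly random neighbourhood sector —
the knob that degrades the directedness statistics without changing the
wave mechanics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import QUIESCENT_REL
from .neighborhood import WAVE_DIR_SECTOR, sector_of

__all__ = [
    "AgentSet",
    "WaveParams",
    "RenderParams",
    "SimulationTruth",
    "build_lattice",
    "simulate_wave",
    "render_frames",
    "tracks_from_agents",
]


@dataclass
class AgentSet:
    """A set of agents on the nest plane.

    ``table`` columns: agent_id (unique int), x_mm, y_mm, z_mm (~0),
    x_px, y_px (derived via ``mm_per_px``, rounded half-up consistently).
    """

    table: pd.DataFrame
    mm_per_px: float = 0.30
    min_spacing_mm: float = 10.0

    def __post_init__(self) -> None:
        t = self.table
        if t["agent_id"].duplicated().any():
            raise ValueError("agent ids must be unique")
        if len(t) > 1:
            xy = t[["x_mm", "y_mm"]].to_numpy(float)
            d = np.hypot(xy[:, None, 0] - xy[None, :, 0],
                         xy[:, None, 1] - xy[None, :, 1])
            np.fill_diagonal(d, np.inf)
            if d.min() < self.min_spacing_mm:
                raise ValueError(
                    f"pairwise distance {d.min():.2f} mm below "
                    f"min_spacing {self.min_spacing_mm} mm"
                )

    def __len__(self) -> int:
        return len(self.table)

    @property
    def ids(self) -> np.ndarray:
        return self.table["agent_id"].to_numpy()


@dataclass(frozen=True)
class WaveParams:
    """Parameters of one simulated shimmering episode.

    dir_true
        Key direction (1-4) the wave spreads in (1 = from Right to Left,
        2 = Bottom to Top, 3 = Left to Right, 4 = Top to Bottom).
    p_directed
        Probability that a join's recorded trigger is the nearest
        previously active near neighbour; otherwise a uniformly random
        sector (1-8) is recorded.
    k_couple
        Graduality coefficient: slope of an agent's pulse peak (excess
        over baseline) on its trigger's peak. 0 = independent amplitudes,
        1 = identity transfer.
    latency_frames
        Frames between a trigger's onset and the triggered agent's onset.
    refractory_ms
        Dead time after an agent's onset during which it cannot rejoin.
    pulse_ms
        Duration of the raised-cosine abdomen-flip pulse (200 ms = 12
        frames at 60 fps).
    base_amp, amp_sd
        Mean and s.d. of the per-incident intrinsic peak excess (rel
        units above the quiescent level ~1.08); the default puts peaks
        near 3x the quiescent level, i.e. mid wave-strength levels.
    tail_amp, tail_period_ms, tail_decay_ms
        Damped post-flip oscillation, as a fraction of the pulse peak.
    noise_sd
        Baseline motion noise s.d. added to every trace sample.
    """

    dir_true: int = 3
    p_directed: float = 1.0
    k_couple: float = 0.5
    latency_frames: int = 3
    refractory_ms: float = 800.0
    pulse_ms: float = 200.0
    base_amp: float = 2.5
    amp_sd: float = 0.6
    tail_amp: float = 0.2
    tail_period_ms: float = 150.0
    tail_decay_ms: float = 120.0
    noise_sd: float = 0.05
    baseline: float = QUIESCENT_REL
    fps: float = 60.0
    near_radius_mm: float = 40.0
    far_radius_mm: float = 100.0
    trigger_window_frames: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_directed <= 1.0:
            raise ValueError("p_directed must lie in [0, 1]")
        if self.refractory_ms <= self.pulse_ms:
            raise ValueError("refractory_ms must exceed pulse_ms")
        if self.latency_frames < 1:
            raise ValueError("latency_frames must be >= 1")
        if self.dir_true not in WAVE_DIR_SECTOR:
            raise ValueError("dir_true must be a key direction 1-4")

    @property
    def frame_ms(self) -> float:
        return 1000.0 / self.fps

    @property
    def pulse_frames(self) -> int:
        return int(round(self.pulse_ms / self.frame_ms))

    @property
    def refractory_frames(self) -> int:
        return int(round(self.refractory_ms / self.frame_ms))


@dataclass
class SimulationTruth:
    """Ground truth of a simulated episode.

    edges
        One row per non-generator activation: dst (triggered agent), src
        (mechanically triggering agent: the nearest qualifying near
        neighbour), frame (dst onset), recorded_trigger / recorded_sector
        (the attribution the analysis should recover; differs from the
        mechanical one with probability 1 - p_directed), wave (0-based
        wave index).
    incidents
        One row per activation incl. generators: agent_id, t0, peak_rel,
        peak_excess, is_generator, wave.
    """

    dir_true: int
    edges: pd.DataFrame
    incidents: pd.DataFrame
    params: WaveParams
    empty: bool = False

    def to_incidents(self, cws_bounds=None) -> pd.DataFrame:
        """Analysis-ready incident table built from the ground truth.

        Uses the true onsets, peaks and *recorded* trigger attributions
        (so with p_directed < 1 the trigger sectors are partly random),
        bypassing detection and assignment: the oracle input for
        recovery tests of the directedness statistics.
        """
        from .detect import categorize_ws

        if cws_bounds is None:
            cws_bounds = tuple(
                m * self.params.baseline
                for m in (1.5, 2.0, 3.0, 4.5, 6.5, 9.0, 12.0, 16.0)
            )
        inc = self.incidents.copy()
        inc["c_ws"] = categorize_ws(inc["peak_rel"].to_numpy(), cws_bounds)
        inc["wave_id"] = inc["wave"]
        rec = self.edges.set_index(["dst", "wave"])
        trig, sec = [], []
        for row in inc.itertuples(index=False):
            key = (int(row.agent_id), int(row.wave))
            if key in rec.index:
                e = rec.loc[key]
                trig.append(int(np.atleast_1d(e["recorded_trigger"])[0]))
                sec.append(int(np.atleast_1d(e["recorded_sector"])[0]))
            else:
                trig.append(None)
                sec.append(None)
        inc["trigger_id"] = pd.array(trig, dtype="Int64")
        inc["dir_trig"] = pd.array(sec, dtype="Int64")
        inc["role"] = np.where(inc["trigger_id"].notna(), "focus", "untriggered-active")
        inc["dir_wav"] = self.dir_true
        return inc


def build_lattice(
    extent_mm: tuple[float, float],
    spacing_mm: float = 29.0,
    jitter_sd: float = 0.0,
    seed: int = 0,
    mm_per_px: float = 0.30,
    min_spacing_mm: float = 10.0,
    origin_mm: tuple[float, float] = (20.0, 20.0),
) -> AgentSet:
    """Hexagonal agent lattice with Gaussian positional jitter.

    The default 29 mm spacing puts 6 agents inside the open 40 mm disc
    around an interior agent, matching the occupancy of the near
    neighbourhood (a handful of bees) at the density of a quiescent nest
    surface. Jitter displacements are truncated at
    ``(spacing - min_spacing) / 2`` so pairwise distances never fall
    below ``min_spacing_mm``.

    An extent smaller than the spacing yields a single-agent set with a
    warning rather than an error. ``origin_mm`` shifts the lattice away
    from the image origin so every agent's ROI fits inside rendered
    frames (20 mm ~ 67 px at the default scale).
    """
    W, H = float(extent_mm[0]), float(extent_mm[1])
    if spacing_mm <= 0 or W <= 0 or H <= 0:
        raise ValueError("extent and spacing must be positive")
    rng = np.random.default_rng(seed)
    dy = spacing_mm * np.sqrt(3.0) / 2.0
    xs, ys = [], []
    row = 0
    y = 0.0
    while y <= H + 1e-9:
        x0 = (spacing_mm / 2.0) if (row % 2) else 0.0
        x = x0
        while x <= W + 1e-9:
            xs.append(x)
            ys.append(y)
            x += spacing_mm
        y += dy
        row += 1
    xs = np.asarray(xs)
    ys = np.asarray(ys)
    if len(xs) == 1:
        warnings.warn("extent smaller than spacing: single-agent set")
    if jitter_sd > 0:
        cap = max((spacing_mm - min_spacing_mm) / 2.0, 0.0)
        jit = rng.normal(0.0, jitter_sd, size=(len(xs), 2))
        norm = np.hypot(jit[:, 0], jit[:, 1])
        over = norm > cap
        if cap == 0:
            jit[:] = 0.0
        elif over.any():
            jit[over] *= (cap / norm[over])[:, None]
        xs = xs + jit[:, 0]
        ys = ys + jit[:, 1]
    xs = xs + origin_mm[0]
    ys = ys + origin_mm[1]
    table = pd.DataFrame(
        {
            "agent_id": np.arange(len(xs), dtype=int),
            "x_mm": xs,
            "y_mm": ys,
            "z_mm": np.zeros(len(xs)),
        }
    )
    table["x_px"] = np.floor(table["x_mm"] / mm_per_px + 0.5).astype(int)
    table["y_px"] = np.floor(table["y_mm"] / mm_per_px + 0.5).astype(int)
    return AgentSet(table, mm_per_px=mm_per_px, min_spacing_mm=min_spacing_mm)


def _generator_ids(agents: AgentSet, dir_true: int, spacing_hint: float) -> np.ndarray:
    """Generator cohort: the strip of agents on the edge the wave comes from."""
    t = agents.table
    x, y = t["x_mm"].to_numpy(), t["y_mm"].to_numpy()
    tol = 0.75 * spacing_hint
    if dir_true == 3:       # from Left to Right: cohort at left edge
        mask = x <= x.min() + tol
    elif dir_true == 1:     # from Right to Left
        mask = x >= x.max() - tol
    elif dir_true == 2:     # from Bottom to Top (y down: bottom = max y)
        mask = y >= y.max() - tol
    else:                   # from Top to Bottom
        mask = y <= y.min() + tol
    return t.loc[mask, "agent_id"].to_numpy()


def _median_nn_spacing(xy: np.ndarray) -> float:
    if len(xy) < 2:
        return 1.0
    d = np.hypot(xy[:, None, 0] - xy[None, :, 0], xy[:, None, 1] - xy[None, :, 1])
    np.fill_diagonal(d, np.inf)
    return float(np.median(d.min(axis=1)))


def simulate_wave(
    agents: AgentSet,
    params: WaveParams,
    n_waves: int = 1,
    drive_interval_frames: int | None = None,
    start_frame: int = 30,
    n_frames: int | None = None,
    generator_ids: np.ndarray | None = None,
) -> tuple[pd.DataFrame, SimulationTruth]:
    """Simulate shimmering waves over an agent set.

    Returns ``(strengths, truth)`` where ``strengths`` is a wide frame x
    agent DataFrame of rel_xymov-scale motion strength and ``truth`` the
    :class:`SimulationTruth`. ``n_waves`` successive waves are launched
    every ``drive_interval_frames`` frames. The default interval lets
    each wave cross the whole lattice and every agent leave its
    refractory phase before the next launch (cleanly separated waves);
    pass ``drive_interval_frames=params.refractory_frames`` for
    saturation driving, where agents re-fire as soon as their refractory
    phase expires. Seeded runs are bit-reproducible.
    """
    rng = np.random.default_rng(params.seed)
    t = agents.table
    ids = t["agent_id"].to_numpy()
    n = len(ids)
    idx_of = {int(a): i for i, a in enumerate(ids)}
    xy = t[["x_mm", "y_mm"]].to_numpy(float)

    dist = np.hypot(xy[:, None, 0] - xy[None, :, 0], xy[:, None, 1] - xy[None, :, 1])
    np.fill_diagonal(dist, np.inf)
    near = dist < params.near_radius_mm
    far = dist < params.far_radius_mm

    spacing = _median_nn_spacing(xy)
    if generator_ids is None:
        generator_ids = _generator_ids(agents, params.dir_true, spacing)
    gen_idx = np.array([idx_of[int(g)] for g in generator_ids], dtype=int)
    if gen_idx.size == 0:
        raise ValueError("no generator agents designated")

    # longest chain ~ lattice span / spacing steps of latency frames each
    span = max(np.ptp(xy[:, 0]), np.ptp(xy[:, 1]))
    cross = int(np.ceil(span / max(spacing, 1e-9))) * params.latency_frames
    if drive_interval_frames is None:
        drive_interval_frames = cross + params.refractory_frames + 2 * params.pulse_frames
    if n_frames is None:
        n_frames = (
            start_frame
            + (n_waves - 1) * drive_interval_frames
            + cross
            + 3 * params.pulse_frames
            + params.refractory_frames // 2
        )

    wave_starts = [start_frame + k * drive_interval_frames for k in range(n_waves)]

    last_t0 = np.full(n, -10**9, dtype=int)     # most recent onset per agent
    peak_excess = np.zeros(n)                   # excess of most recent pulse
    onset_frame = {}                            # frame -> list of agent indices
    incidents: list[dict] = []
    edges: list[dict] = []
    current_wave = -1

    lat = params.latency_frames
    win = params.trigger_window_frames
    refr = params.refractory_frames

    def draw_base() -> float:
        return max(float(rng.normal(params.base_amp, params.amp_sd)), 0.3)

    def activate(i: int, f: int, excess: float, is_gen: bool, wave: int) -> None:
        last_t0[i] = f
        peak_excess[i] = excess
        onset_frame.setdefault(f, []).append(i)
        incidents.append(
            {
                "agent_id": int(ids[i]),
                "t0": int(f),
                "peak_excess": float(excess),
                "peak_rel": float(params.baseline + excess),
                "is_generator": bool(is_gen),
                "wave": int(wave),
            }
        )

    for f in range(n_frames):
        # launch generator cohort(s)
        if f in wave_starts:
            current_wave += 1
            for i in gen_idx:
                if f - last_t0[i] >= refr:
                    activate(i, f, draw_base(), True, current_wave)
        # chain joins: a neighbour reached age == latency this frame
        due = onset_frame.get(f - lat, [])
        if not due:
            continue
        due_set = set(due)
        candidates = set()
        for j in due_set:
            candidates.update(np.flatnonzero(near[j]))
        for i in sorted(candidates):
            if f - last_t0[i] < refr or last_t0[i] == f:
                continue
            # mechanical trigger: nearest near-neighbour active in window
            nb = np.flatnonzero(near[i])
            age = f - last_t0[nb]
            ok = (age >= 1) & (age <= win)
            if not any(last_t0[nb[ok]] == f - lat):
                continue  # joins fire exactly at trigger age == latency
            nb = nb[ok]
            order = np.lexsort((ids[nb], last_t0[nb], dist[i, nb]))
            src = nb[order[0]]
            excess = (
                params.k_couple * peak_excess[src]
                + (1.0 - params.k_couple) * draw_base()
            )
            activate(i, f, excess, False, current_wave)
            if rng.random() < params.p_directed:
                rec_src, rec_sector = src, sector_of(xy[i], xy[src])
            else:
                rec_sector = int(rng.integers(1, 9))
                rec_src = src
                # nearest previously active far neighbour in that sector
                fb = np.flatnonzero(far[i])
                fage = f - last_t0[fb]
                fok = fb[(fage >= 1) & (fage <= win)]
                in_sec = [
                    j for j in fok if sector_of(xy[i], xy[j]) == rec_sector
                ]
                if in_sec:
                    rec_src = min(in_sec, key=lambda j: dist[i, j])
            edges.append(
                {
                    "src": int(ids[src]),
                    "dst": int(ids[i]),
                    "frame": int(f),
                    "recorded_trigger": int(ids[rec_src]),
                    "recorded_sector": int(rec_sector),
                    "wave": int(current_wave),
                }
            )

    inc = pd.DataFrame(
        incidents,
        columns=["agent_id", "t0", "peak_excess", "peak_rel", "is_generator", "wave"],
    )
    edge_df = pd.DataFrame(
        edges,
        columns=["src", "dst", "frame", "recorded_trigger", "recorded_sector", "wave"],
    )
    n_joined = 0 if inc.empty else int((~inc["is_generator"]).sum())
    empty = n_joined == 0 and n > len(gen_idx)
    if empty:
        warnings.warn("no agent reachable from the generator cohort: empty wave")

    strengths = _render_strengths(inc, ids, idx_of, n_frames, params, rng)
    truth = SimulationTruth(
        dir_true=params.dir_true,
        edges=edge_df,
        incidents=inc,
        params=params,
        empty=bool(empty),
    )
    return strengths, truth


def _render_strengths(inc, ids, idx_of, n_frames, params: WaveParams, rng):
    """Raised-cosine pulses + damped oscillation tail + baseline noise."""
    n = len(ids)
    arr = np.full((n_frames, n), float(params.baseline))
    pf = params.pulse_frames
    tt = np.arange(pf + 1)
    pulse_shape = 0.5 * (1.0 - np.cos(2.0 * np.pi * tt / pf))
    # damped oscillation appended after the pulse
    tail_len = int(round(3.0 * params.tail_decay_ms / params.frame_ms))
    ts = np.arange(1, tail_len + 1) * params.frame_ms
    tail_shape = (
        params.tail_amp
        * np.exp(-ts / params.tail_decay_ms)
        * np.cos(2.0 * np.pi * ts / params.tail_period_ms)
    )
    for row in inc.itertuples(index=False):
        i = idx_of[int(row.agent_id)]
        f0 = int(row.t0)
        hi = min(f0 + pf + 1, n_frames)
        arr[f0:hi, i] += row.peak_excess * pulse_shape[: hi - f0]
        t_end = f0 + pf + 1
        hi2 = min(t_end + tail_len, n_frames)
        if hi2 > t_end:
            arr[t_end:hi2, i] += row.peak_excess * tail_shape[: hi2 - t_end]
    if params.noise_sd > 0:
        arr += rng.normal(0.0, params.noise_sd, size=arr.shape)
    np.clip(arr, 0.0, None, out=arr)
    return pd.DataFrame(arr, columns=pd.Index(ids, name="agent_id"))


@dataclass(frozen=True)
class RenderParams:
    """Frame-rendering geometry and noise.

    Agents are drawn as two bright ellipses (thorax + abdomen); the
    abdomen tip displaces upward proportionally to the instantaneous
    strength excess. At 0.30 mm/px the 6 mm abdomen is ~20 px wide.
    The per-pixel background noise s.d. of 2.66 grey levels makes the
    quiescent difference image average ~3 grey levels per pixel
    (E|a-b| = 2*sd/sqrt(pi)), i.e. a quiescent ROI sum of ~1.08e4.
    """

    mm_per_px: float = 0.30
    abdomen_width_mm: float = 6.0
    abdomen_length_mm: float = 9.0
    background: int = 30
    body_level: int = 200
    noise_sd: float = 2.66
    displacement_gain_px: float = 12.0
    max_lift_px: float = 24.0
    margin_px: int = 40
    seed: int = 0

    @property
    def abdomen_width_px(self) -> int:
        return int(round(self.abdomen_width_mm / self.mm_per_px))

    @property
    def abdomen_length_px(self) -> int:
        return int(round(self.abdomen_length_mm / self.mm_per_px))


def render_frames(
    agents: AgentSet,
    strengths: pd.DataFrame,
    render: RenderParams | None = None,
    baseline: float = QUIESCENT_REL,
) -> np.ndarray:
    """Render a strength table as an 8-bit grayscale frame stack.

    Returns an array of shape (n_frames, H, W), dtype uint8. Rendering is
    deterministic apart from the seeded background noise: two consecutive
    identical strength rows with zero noise produce identical pixels.
    Overlapping glyphs are allowed (later agents overdraw).
    """
    from skimage.draw import ellipse

    render = render or RenderParams()
    t = agents.table
    xs = t["x_px"].to_numpy()
    ys = t["y_px"].to_numpy()
    W = int(xs.max()) + render.margin_px + 1
    H = int(ys.max()) + render.margin_px + 1
    if xs.min() < render.margin_px // 2 or ys.min() < render.margin_px // 2:
        # shift so all ROIs fit; positions in the track table must match
        raise ValueError("agent positions too close to frame origin; add margin")
    cols = list(strengths.columns)
    order = [list(t["agent_id"]).index(a) for a in cols]
    n_frames = len(strengths)
    rng = np.random.default_rng(render.seed)
    stack = np.empty((n_frames, H, W), dtype=np.uint8)
    aw = render.abdomen_width_px // 2
    al = render.abdomen_length_px // 2
    vals = strengths.to_numpy(float)
    for f in range(n_frames):
        frame = np.full((H, W), float(render.background))
        if render.noise_sd > 0:
            frame += rng.normal(0.0, render.noise_sd, size=frame.shape)
        for k, j in enumerate(order):
            cx, cy = int(xs[j]), int(ys[j])
            # thorax: small static disc
            rr, cc = ellipse(cy, cx, 6, 6, shape=frame.shape)
            frame[rr, cc] = render.body_level
            # abdomen below the thorax; tip lifts with motion strength.
            # Lift is capped so the glyph never leaves the 60x60 px ROI
            # (increasing strength then saturates, never reduces, the
            # difference-image sum).
            lift = min(
                render.displacement_gain_px * max(vals[f, k] - baseline, 0.0),
                render.max_lift_px,
            )
            ay = cy + 10 - lift
            rr, cc = ellipse(ay, cx, al, aw, shape=frame.shape)
            frame[rr, cc] = min(render.body_level + 30, 255)
        stack[f] = np.clip(frame, 0, 255).astype(np.uint8)
    return stack


def tracks_from_agents(agents: AgentSet, n_frames: int) -> pd.DataFrame:
    """Per-frame track table (frame, agent_id, x_px, y_px, x_mm, y_mm, z_mm)."""
    t = agents.table
    frames = np.repeat(np.arange(n_frames), len(t))
    rep = pd.concat([t] * n_frames, ignore_index=True)
    out = pd.DataFrame(
        {
            "frame": frames,
            "agent_id": rep["agent_id"],
            "x_px": rep["x_px"],
            "y_px": rep["y_px"],
            "x_mm": rep["x_mm"],
            "y_mm": rep["y_mm"],
            "z_mm": rep["z_mm"],
        }
    )
    return out
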