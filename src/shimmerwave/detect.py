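"""Wave-incident detection, wave-strength levels and repetition rate.

A wave incident is one supra-threshold abdomen-flipping episode of one
agent. Its onset is anchored at t1, the first frame of a run of at least
five consecutive frames whose supra-baseline excess exceeds the
participation threshold (one normalized unit, i.e. 1e4 raw-sum units);
the time zero t0 is defined one frame before t1. The five-frame rule
excludes noise-triggered events. Peak strength within the run is mapped
onto eight ordinal wave-strength levels (c_ws = 1-8; c_ws = 0 means
non-participation).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "detect_incidents",
    "detect_all",
    "categorize_ws",
    "agent_baseline",
    "repetition_rate",
]


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """(start, stop) positional index pairs of True runs, stop exclusive."""
    if mask.size == 0:
        return []
    padded = np.concatenate([[False], mask, [False]])
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    stops = np.flatnonzero(d == -1)
    return list(zip(starts, stops))


def detect_incidents(
    trace: pd.Series,
    baseline: float,
    threshold: float = 1.0,
    min_run_frames: int = 5,
    merge_frames: int = 48,
) -> pd.DataFrame:
    """Detect wave incidents in one agent's motion trace.

    ``trace`` is rel_xymov indexed by frame (contiguous integers). An
    incident requires excess = trace - baseline strictly above
    ``threshold`` for at least ``min_run_frames`` consecutive frames; its
    t1 is the first such frame and t0 = t1 - 1. Qualifying runs whose
    onsets are closer than ``merge_frames`` (the refractory window) merge
    into a single incident. NaN samples (tracking gaps) break runs.

    Returns a DataFrame with columns t0, t1, peak_rel. An all-baseline
    trace yields an empty frame (valid, not an error).
    """
    if len(trace) < min_run_frames + 1:
        return pd.DataFrame(columns=["t0", "t1", "peak_rel"])
    vals = trace.to_numpy(float)
    frames = trace.index.to_numpy()
    supra = np.where(np.isnan(vals), False, vals - baseline > threshold)
    runs = [(a, b) for a, b in _runs(supra) if b - a >= min_run_frames]
    merged: list[list[int]] = []
    for a, b in runs:
        if merged and a - merged[-1][0] < merge_frames:
            merged[-1][1] = b
        else:
            merged.append([a, b])
    rows = []
    for a, b in merged:
        t1 = int(frames[a])
        rows.append((t1 - 1, t1, float(np.nanmax(vals[a:b]))))
    return pd.DataFrame(rows, columns=["t0", "t1", "peak_rel"])


def agent_baseline(
    trace: pd.Series,
    quiescent_window: tuple[int, int] | None = None,
    fallback: float = 1.08,
) -> float:
    """Per-agent baseline: median over a declared quiescent window.

    Without a declared window the global quiescent level (~1.08) is used;
    the trace median itself is unsafe when waves occupy most of a session.
    """
    if quiescent_window is None:
        return fallback
    lo, hi = quiescent_window
    seg = trace.loc[(trace.index >= lo) & (trace.index < hi)].dropna()
    return float(seg.median()) if len(seg) else fallback


def detect_all(
    wide_traces: pd.DataFrame,
    baseline: float | dict | None = None,
    threshold: float = 1.0,
    min_run_frames: int = 5,
    merge_frames: int = 48,
    quiescent_window: tuple[int, int] | None = None,
    fallback_baseline: float = 1.08,
) -> pd.DataFrame:
    """Detect incidents for every agent of a frames x agents trace table.

    Returns a DataFrame (agent_id, t0, t1, peak_rel) sorted by (t0,
    agent_id). ``baseline`` may be a scalar, a per-agent mapping, or None
    to derive it per agent from ``quiescent_window``.
    """
    frames = []
    for agent in wide_traces.columns:
        tr = wide_traces[agent]
        if baseline is None:
            b = agent_baseline(tr, quiescent_window, fallback_baseline)
        elif isinstance(baseline, dict):
            b = baseline.get(agent, fallback_baseline)
        else:
            b = float(baseline)
        inc = detect_incidents(tr, b, threshold, min_run_frames, merge_frames)
        if not inc.empty:
            inc.insert(0, "agent_id", agent)
            frames.append(inc)
    if not frames:
        return pd.DataFrame(columns=["agent_id", "t0", "t1", "peak_rel"])
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["t0", "agent_id"], ignore_index=True)


def categorize_ws(peak_rel, bounds) -> int | np.ndarray:
    """Wave-strength level c_ws (0-8) of a peak rel_xymov value.

    ``bounds`` are the eight strictly increasing lower level boundaries;
    a peak in the half-open interval [b_i, b_{i+1}) gets level i+1, below
    b_1 level 0 (non-participation), at or above b_8 level 8.
    """
    b = np.asarray(bounds, dtype=float)
    if len(b) != 8 or np.any(np.diff(b) <= 0):
        raise ValueError("bounds must be 8 strictly increasing values")
    c = np.searchsorted(b, np.asarray(peak_rel, dtype=float), side="right")
    if np.isscalar(peak_rel):
        return int(c)
    return c.astype(int)


def repetition_rate(
    incidents: pd.DataFrame,
    fps: float = 60.0,
) -> tuple[float, float]:
    """Wave repetition rate and refractory estimate from incident onsets.

    rate (Hz) = 1 / median inter-t0 interval over all agents with >= 2
    incidents; the refractory period (ms) is estimated by the minimum
    observed inter-t0 interval (under saturation driving agents re-fire
    as soon as the refractory period has elapsed). With fewer than two
    incidents everywhere both values are NaN (reported as missing).
    """
    intervals = []
    for _, g in incidents.groupby("agent_id"):
        t0 = np.sort(g["t0"].to_numpy())
        if len(t0) >= 2:
            intervals.extend(np.diff(t0))
    if not intervals:
        return float("nan"), float("nan")
    intervals = np.asarray(intervals, dtype=float)
    frame_ms = 1000.0 / fps
    rate = 1.0 / (np.median(intervals) * frame_ms / 1000.0)
    refractory_ms = float(intervals.min() * frame_ms)
    return float(rate), refractory_ms
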