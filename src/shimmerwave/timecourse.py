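"""Ensemble time courses, transfer time and propagation speed.

Wave incidents recorded at different nest locations and times are
synchronized on their time zero t0 and averaged into mean +- SE curves
per wave-strength level: one ensemble for the focus bees themselves and
one for their triggering neighbours, the latter aligned to the *focus*
bee's t0 so the horizontal offset between the two rising flanks is the
neighbour-to-focus information transfer time. That offset is read off at
14 threshold levels (rel_xymov 1.0-2.3 in steps of 0.1) by linear
interpolation of the threshold crossings; dividing the mean distance
between the partners by the transfer time gives the propagation speed of
a single bucket-bridging step (62 mm / 47.29 ms ~ 1.311 m/s in the
field data).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "EnsembleCurve",
    "ensemble_curve",
    "synchronize",
    "transfer_time",
    "cross_correlation_lag",
    "propagation_speed",
]


@dataclass
class EnsembleCurve:
    """Mean +- SE motion strength on a relative time grid (0 at t0)."""

    t_ms: np.ndarray
    mean: np.ndarray
    se: np.ndarray
    n: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t_ms": self.t_ms, "mean": self.mean, "se": self.se, "n": self.n}
        )


def ensemble_curve(
    wide_traces: pd.DataFrame,
    anchors: list[tuple[int, int]],
    window_ms: tuple[float, float] = (-200.0, 600.0),
    fps: float = 60.0,
) -> EnsembleCurve:
    """Average trace segments synchronized at per-incident anchor frames.

    ``anchors`` is a list of (agent_id, t0_frame). Segments extending
    beyond a trace are truncated; per-point n bookkeeping keeps the mean
    and SE honest at the window edges. Equals the brute-force average of
    the aligned segments at every grid point.
    """
    frame_ms = 1000.0 / fps
    k0 = int(np.floor(window_ms[0] / frame_ms))
    k1 = int(np.ceil(window_ms[1] / frame_ms))
    grid = np.arange(k0, k1 + 1)
    frames = wide_traces.index.to_numpy()
    fmin, fmax = frames.min(), frames.max()
    segs = np.full((len(anchors), len(grid)), np.nan)
    for m, (agent, t0) in enumerate(anchors):
        if agent not in wide_traces.columns:
            continue
        col = wide_traces[agent]
        want = t0 + grid
        ok = (want >= fmin) & (want <= fmax)
        segs[m, ok] = col.reindex(want[ok]).to_numpy(float)
    n = np.isfinite(segs).sum(axis=0)
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(np.where(np.isfinite(segs), segs, np.nan), axis=0)
        sd = np.nanstd(segs, axis=0, ddof=1)
    se = np.where(n > 1, sd / np.sqrt(np.maximum(n, 1)), 0.0)
    keep = n > 0
    return EnsembleCurve(
        t_ms=grid[keep] * frame_ms, mean=mean[keep], se=se[keep], n=n[keep]
    )


def synchronize(
    wide_traces: pd.DataFrame,
    incidents: pd.DataFrame,
    window_ms: tuple[float, float] = (-200.0, 600.0),
    fps: float = 60.0,
    same_strength: bool = True,
) -> dict[int, dict[str, EnsembleCurve]]:
    """Focus-bee and trigger-neighbour ensembles per wave-strength level.

    Focus curves align each focus incident's trace on its own t0; the
    neighbour curve of a stratum aligns the *trigger's* trace on the
    focus bee's t0, keeping only triggers that flipped at the same wave
    strength level as their focus bee when ``same_strength`` is set.

    Returns {c_ws: {"fb": EnsembleCurve, "nb": EnsembleCurve}} (the "nb"
    key is absent when a stratum has no qualifying trigger pair).
    """
    fb = incidents[incidents["role"] == "focus"]
    peak_lut = incidents.set_index(["agent_id", "wave_id"]).sort_index()
    out: dict[int, dict[str, EnsembleCurve]] = {}
    for c_ws, grp in fb.groupby("c_ws"):
        entry: dict[str, EnsembleCurve] = {}
        anchors = [(a, int(t)) for a, t in zip(grp["agent_id"], grp["t0"])]
        entry["fb"] = ensemble_curve(wide_traces, anchors, window_ms, fps)
        nb_anchors = []
        for row in grp.itertuples(index=False):
            if pd.isna(row.trigger_id):
                continue
            key = (int(row.trigger_id), row.wave_id)
            try:
                trig = peak_lut.loc[key]
            except KeyError:
                continue
            if isinstance(trig, pd.DataFrame):
                trig = trig.iloc[0]
            if same_strength and int(trig["c_ws"]) != int(c_ws):
                continue
            nb_anchors.append((int(row.trigger_id), int(row.t0)))
        if nb_anchors:
            entry["nb"] = ensemble_curve(wide_traces, nb_anchors, window_ms, fps)
        out[int(c_ws)] = entry
    return out


def _rising_crossing(t_ms: np.ndarray, y: np.ndarray, level: float) -> float:
    """First upward crossing time of ``level``, linearly interpolated.

    A curve already above the level at the window start has no observable
    onset for that level: NaN (the threshold gets excluded).
    """
    above = y >= level
    if above[0]:
        return float("nan")
    idx = np.flatnonzero(~above[:-1] & above[1:])
    if idx.size == 0:
        return float("nan")
    i = idx[0]
    y0, y1 = y[i], y[i + 1]
    if y1 == y0:
        return float(t_ms[i + 1])
    frac = (level - y0) / (y1 - y0)
    return float(t_ms[i] + frac * (t_ms[i + 1] - t_ms[i]))


@dataclass
class TransferTime:
    mean_ms: float
    se_ms: float
    per_threshold: pd.DataFrame       # threshold, t_fb_ms, t_nb_ms, dt_ms
    n_used: int
    n_excluded: int
    reliable: bool


def transfer_time(
    fb_curve: EnsembleCurve,
    nb_curve: EnsembleCurve,
    thresholds=tuple(round(1.0 + 0.1 * i, 1) for i in range(14)),
    min_usable: int = 3,
) -> TransferTime:
    """Neighbour-to-focus transfer time from threshold crossings.

    For each threshold level the rising-phase crossing time of both
    ensemble curves is interpolated linearly; their difference
    dt = t_fb - t_nb estimates the transfer time. Thresholds that either
    curve never crosses are excluded (and counted); the estimate is the
    mean +- SE over the remaining levels and flagged unreliable when
    fewer than ``min_usable`` survive. A common time shift of both curves
    leaves the estimate unchanged.
    """
    rows = []
    for th in thresholds:
        t_fb = _rising_crossing(fb_curve.t_ms, fb_curve.mean, th)
        t_nb = _rising_crossing(nb_curve.t_ms, nb_curve.mean, th)
        rows.append((th, t_fb, t_nb, t_fb - t_nb))
    per = pd.DataFrame(rows, columns=["threshold", "t_fb_ms", "t_nb_ms", "dt_ms"])
    usable = per.dropna(subset=["dt_ms"])
    n_used = len(usable)
    dt = usable["dt_ms"].to_numpy()
    mean = float(dt.mean()) if n_used else float("nan")
    se = float(np.std(dt, ddof=1) / np.sqrt(n_used)) if n_used > 1 else 0.0
    return TransferTime(
        mean_ms=mean,
        se_ms=se,
        per_threshold=per,
        n_used=n_used,
        n_excluded=len(per) - n_used,
        reliable=n_used >= min_usable,
    )


def cross_correlation_lag(
    fb_curve: EnsembleCurve,
    nb_curve: EnsembleCurve,
) -> float:
    """Lag (ms) of the focus curve behind the neighbour curve.

    Secondary estimator cross-checking the threshold-crossing transfer
    time: the argmax of the cross-correlation of the *first differences*
    of the ensemble means on their common grid (flank matching; raw
    curves with long plateaus would bias the lag towards zero), refined
    parabolically to sub-frame resolution.
    """
    common = np.intersect1d(fb_curve.t_ms, nb_curve.t_ms)
    if len(common) < 4:
        return float("nan")
    f = np.diff(np.interp(common, fb_curve.t_ms, fb_curve.mean))
    g = np.diff(np.interp(common, nb_curve.t_ms, nb_curve.mean))
    common = common[1:]
    f = f - f.mean()
    g = g - g.mean()
    corr = np.correlate(f, g, mode="full")
    lags = np.arange(-len(common) + 1, len(common))
    i = int(np.argmax(corr))
    # parabolic refinement around the integer-lag peak
    if 0 < i < len(corr) - 1:
        denom = corr[i - 1] - 2 * corr[i] + corr[i + 1]
        delta = 0.5 * (corr[i - 1] - corr[i + 1]) / denom if denom != 0 else 0.0
    else:
        delta = 0.0
    step = float(np.median(np.diff(common)))
    return float((lags[i] + delta) * step)


def propagation_speed(
    mean_distance_mm: float,
    transfer_ms: float,
    transfer_se_ms: float = 0.0,
) -> tuple[float, float]:
    """Propagation speed (m/s) of one bucket-bridging step.

    mm/ms equals m/s, so speed = distance / time directly; the SE is
    propagated from the transfer-time SE (first-order).
    """
    if mean_distance_mm <= 0 or transfer_ms <= 0:
        raise ValueError("distance and transfer time must be positive")
    speed = mean_distance_mm / transfer_ms
    se = mean_distance_mm / transfer_ms**2 * transfer_se_ms
    return float(speed), float(se)
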