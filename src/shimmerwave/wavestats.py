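"""Linearity and continuity statistics of wave propagation.

Linearity (the directed-trigger hypothesis): focus bees should be
triggered preferentially from the direction the wave came from. The
incident counts per trigger sector, normalized within each wave
direction, are tested for coincidence of their supra-median sectors with
the wave-origin window (+-45 deg), and the directedness share is
integrated either above the polynomial-fit minimum (the "fuzziness"
level, estimate A) or above the median level (estimate B).

Continuity (the active-neighbours hypothesis): the sector of a focus
bee's trigger should also hold the majority of her previously active
far neighbours. Active-neighbour counts are binned by angular deviation
from the trigger sector; the excess of the central bin over its
neighbours quantifies continuity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .neighborhood import WAVE_DIR_SECTOR, sector_of_angle, sector_offset

__all__ = [
    "LinearityResult",
    "ContinuityResult",
    "linearity_histogram",
    "test_coincidence",
    "fit_sector_polynomial",
    "estimate_linearity",
    "linearity_analysis",
    "continuity_profile",
]

OFFSET_BINS_DEG = tuple(45 * k for k in range(-3, 5))  # -135 .. +180


@dataclass
class LinearityResult:
    rel_n_fb: pd.DataFrame            # dir_wav x dir_trig, max 1 per row
    counts: pd.DataFrame              # raw counts
    poly: dict                        # dir_wav -> coefficients (np.polyfit order)
    poly_min: dict                    # dir_wav -> fuzziness level
    median_level: dict                # dir_wav -> median rel_n_fb
    estimate_A: dict                  # dir_wav -> percent
    estimate_B: dict                  # dir_wav -> percent
    coincidence: dict                 # dir_wav -> bool

    @property
    def estimate_A_mean(self) -> float:
        return float(np.mean(list(self.estimate_A.values())))

    @property
    def estimate_B_mean(self) -> float:
        return float(np.mean(list(self.estimate_B.values())))


@dataclass
class ContinuityResult:
    rel_n_nh: pd.DataFrame            # c_ws x offset bins, max 1 per row
    mean_counts: pd.DataFrame         # mean active neighbours per focus bee
    excess_rate: dict                 # c_ws -> percent
    excess_rate_pooled: float
    n_focus: pd.Series


def linearity_histogram(incidents: pd.DataFrame, cws_range=(1, 6)) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Trigger-direction histogram, normalized within each wave direction.

    Pools focus incidents over c_ws levels ``cws_range`` (inclusive),
    counts them per (dir_wav, dir_trig) and divides by the maximum count
    within each dir_wav stratum, so max rel_n_fb = 1 per wave direction.
    Returns ``(rel_n_fb, counts)`` as dir_wav x dir_trig(1..8) frames.
    Wave-direction strata without any focus incident are omitted with a
    warning.
    """
    fb = incidents[
        (incidents["role"] == "focus")
        & incidents["dir_trig"].notna()
        & incidents["dir_wav"].notna()
        & incidents["c_ws"].between(*cws_range)
    ]
    all_strata = {int(d) for d in incidents["dir_wav"].dropna().unique()}
    counts = (
        fb.groupby(["dir_wav", "dir_trig"]).size().unstack(fill_value=0)
        .reindex(columns=range(1, 9), fill_value=0)
    )
    counts.columns = counts.columns.astype(int)
    counts.index = counts.index.astype(int)
    present = counts.index[counts.sum(axis=1) > 0]
    dropped = all_strata - set(present)
    if dropped:
        warnings.warn(f"empty wave-direction strata omitted: {sorted(dropped)}")
    counts = counts.loc[present]
    rel = counts.div(counts.max(axis=1), axis=0)
    return rel, counts


def test_coincidence(rel_n_fb: pd.DataFrame) -> dict[int, bool]:
    """Does the supra-median trigger mass coincide with the wave origin?

    For each wave direction the critical window is the wave-origin sector
    +-45 deg (three sectors; the manual wave labelling carries a similar
    tolerance). With eight distinct values exactly four sectors lie
    strictly above the median, so literal containment of every
    supra-median sector in a three-sector window is unattainable;
    coincidence is therefore declared when (a) the maximum sector lies in
    the window and (b) the supra-median excess (rel_n_fb - median,
    summed over strictly supra-median sectors) inside the window strictly
    exceeds the excess outside it. A flat histogram has no strictly
    supra-median sector and returns FALSE.
    """
    out: dict[int, bool] = {}
    for dir_wav, row in rel_n_fb.iterrows():
        med = float(row.median())
        above = {int(s): float(v) - med for s, v in row.items() if v > med}
        key = WAVE_DIR_SECTOR[int(dir_wav)]
        window = {(key - 2) % 8 + 1, key, key % 8 + 1}
        if not above:
            out[int(dir_wav)] = False
            continue
        argmax = int(row.idxmax())
        inside = sum(v for s, v in above.items() if s in window)
        outside = sum(v for s, v in above.items() if s not in window)
        out[int(dir_wav)] = argmax in window and inside > outside
    return out


def fit_sector_polynomial(rel_row: pd.Series, dir_wav: int, degree: int = 4):
    """Fit a polynomial to rel_n_fb over the trigger angle.

    Sector centre angles are re-expressed relative to the wave-origin
    angle (offsets -135..+180 deg) so the circular histogram unwraps onto
    a linear axis centred on the expected maximum. Returns
    ``(coefficients, poly_min)`` with the minimum evaluated over the
    fitted range and clipped at zero.
    """
    key = WAVE_DIR_SECTOR[int(dir_wav)]
    x = np.array([45.0 * sector_offset(int(s), key) for s in rel_row.index])
    order = np.argsort(x)
    x, y = x[order], rel_row.to_numpy(float)[order]
    degree = min(degree, len(x) - 1)
    coef = np.polyfit(x, y, degree)
    grid = np.linspace(x.min(), x.max(), 721)
    pmin = float(np.polyval(coef, grid).min())
    return coef, max(pmin, 0.0)


def estimate_linearity(
    rel_values,
    poly_min: float | None = None,
    median_level: float | None = None,
    dir_wav: int | None = None,
    degree: int = 4,
) -> tuple[float, float]:
    """Directedness shares above the fuzziness level and above the median.

    estimate_A integrates the normalized excess above the polynomial
    minimum (the fuzziness level); estimate_B the excess above the median
    level. Both are percentages of the stratum's total of identified wave
    incidents (the sum of its rel_n_fb values). ``poly_min`` and
    ``median_level`` may be supplied directly; otherwise they are derived
    (the polynomial fit needs ``dir_wav`` for the angular unwrapping).
    estimate_B <= estimate_A whenever poly_min <= median.
    """
    rel = pd.Series(rel_values) if not isinstance(rel_values, pd.Series) else rel_values
    if poly_min is None:
        if dir_wav is None:
            raise ValueError("dir_wav required to fit the polynomial")
        _, poly_min = fit_sector_polynomial(rel, dir_wav, degree)
    poly_min = max(float(poly_min), 0.0)
    if median_level is None:
        median_level = float(rel.median())
    total = float(rel.sum())
    if total == 0:
        return 0.0, 0.0
    a = float(np.clip(rel - poly_min, 0.0, None).sum()) / total * 100.0
    b = float(np.clip(rel - median_level, 0.0, None).sum()) / total * 100.0
    return a, b


def linearity_analysis(
    incidents: pd.DataFrame,
    cws_range=(1, 6),
    degree: int = 4,
) -> LinearityResult:
    """Full linearity work-up: histogram, coincidence test, estimates."""
    rel, counts = linearity_histogram(incidents, cws_range)
    coincidence = test_coincidence(rel)
    poly, pmin, med, est_a, est_b = {}, {}, {}, {}, {}
    for dir_wav, row in rel.iterrows():
        d = int(dir_wav)
        poly[d], pmin[d] = fit_sector_polynomial(row, d, degree)
        med[d] = float(row.median())
        est_a[d], est_b[d] = estimate_linearity(
            row, poly_min=pmin[d], median_level=med[d]
        )
    return LinearityResult(
        rel_n_fb=rel,
        counts=counts,
        poly=poly,
        poly_min=pmin,
        median_level=med,
        estimate_A=est_a,
        estimate_B=est_b,
        coincidence=coincidence,
    )


def continuity_profile(
    incidents: pd.DataFrame,
    agents: pd.DataFrame,
    far_radius_mm: float = 100.0,
    window_frames: int = 15,
    cws_range=(1, 5),
) -> ContinuityResult:
    """Active-neighbour profile around the trigger direction.

    For every focus incident with a trigger direction, previously active
    far neighbours (strictly inside ``far_radius_mm``, same wave, onset
    1..``window_frames`` frames before the focus onset) are binned by the
    sector offset of their position from the trigger sector (45-deg bins,
    -135..+180). Counts are averaged per focus incident within each c_ws
    stratum and normalized to max 1 per stratum. The excess rate is
    (n(0) - mean of the two adjacent bins) / n(0) x 100.
    """
    pos = agents.set_index("agent_id")[["x_mm", "y_mm"]]
    fb = incidents[
        (incidents["role"] == "focus")
        & incidents["dir_trig"].notna()
        & incidents["c_ws"].between(*cws_range)
    ]
    all_inc = incidents
    xy = pos.loc[all_inc["agent_id"]].to_numpy(float)
    t0 = all_inc["t0"].to_numpy()
    wave = all_inc["wave_id"].to_numpy()
    aid = all_inc["agent_id"].to_numpy()

    bins = {b: i for i, b in enumerate(OFFSET_BINS_DEG)}
    strata = sorted(fb["c_ws"].unique())
    counts = np.zeros((len(strata), len(OFFSET_BINS_DEG)))
    n_focus = {int(c): 0 for c in strata}
    srow = {c: i for i, c in enumerate(strata)}

    for row in fb.itertuples(index=False):
        fxy = pos.loc[row.agent_id].to_numpy(float)
        dt = row.t0 - t0
        mask = (dt >= 1) & (dt <= window_frames) & (wave == row.wave_id) & (aid != row.agent_id)
        if not mask.any():
            n_focus[int(row.c_ws)] += 1
            continue
        j = np.flatnonzero(mask)
        dx = xy[j, 0] - fxy[0]
        dy = xy[j, 1] - fxy[1]
        dmask = np.hypot(dx, dy) < far_radius_mm
        j, dx, dy = j[dmask], dx[dmask], dy[dmask]
        n_focus[int(row.c_ws)] += 1
        if len(j) == 0:
            continue
        sec = sector_of_angle(np.degrees(np.arctan2(dy, dx)))
        for s in np.atleast_1d(sec):
            off = 45 * sector_offset(int(s), int(row.dir_trig))
            counts[srow[row.c_ws], bins[off]] += 1

    idx = pd.Index([int(c) for c in strata], name="c_ws")
    cols = pd.Index(OFFSET_BINS_DEG, name="delta_alpha_deg")
    nf = pd.Series({int(c): n_focus[int(c)] for c in strata}, name="n_focus")
    mean_counts = pd.DataFrame(counts, index=idx, columns=cols).div(
        nf.replace(0, np.nan), axis=0
    )
    maxima = mean_counts.max(axis=1)
    rel = mean_counts.div(maxima.replace(0, np.nan), axis=0)

    def _excess(rowvals: pd.Series) -> float:
        centre = rowvals.get(0, np.nan)
        adj = np.nanmean([rowvals.get(-45, np.nan), rowvals.get(45, np.nan)])
        if not np.isfinite(centre) or centre == 0:
            return float("nan")
        return float((centre - adj) / centre * 100.0)

    excess = {int(c): _excess(mean_counts.loc[c]) for c in idx}
    pooled = mean_counts.mul(nf, axis=0).sum(axis=0) / nf.sum()
    return ContinuityResult(
        rel_n_nh=rel,
        mean_counts=mean_counts,
        excess_rate=excess,
        excess_rate_pooled=_excess(pooled),
        n_focus=nf,
    )
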