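"""Neighbourhoods, angular sectors and trigger assignment.

The analysis partitions the surroundings of each focus bee into eight
45-degree sectors in image coordinates (x rightward, y downward), numbered
clockwise from "from Right" (sector 1, centred at 0 deg) through "from
Bottom" (3, 90 deg), "from Left" (5, 180 deg) and "from Top" (7, 270 deg).
The four key wave directions map onto the cardinal sectors:
dir_WAV 1 (from Right to Left) <-> sector 1, 2 (Bottom to Top) <-> 3,
3 (Left to Right) <-> 5, and 4 (Top to Bottom) <-> 7.

A focus bee's trigger is the spatially closest near-neighbour (distance
< 40 mm, strictly) that joined the same wave at most five frames earlier;
the sector containing that neighbour is the focus bee's trigger direction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: Centre angle (deg, image coordinates, y down) of each of the 8 sectors.
SECTOR_CENTRE_DEG = {s: 45.0 * (s - 1) for s in range(1, 9)}

#: Key wave direction -> the sector whose centre is the wave's origin angle.
WAVE_DIR_SECTOR = {1: 1, 2: 3, 3: 5, 4: 7}

#: Key wave direction -> origin angle alpha_WAV in degrees.
WAVE_DIR_ANGLE = {d: SECTOR_CENTRE_DEG[s] for d, s in WAVE_DIR_SECTOR.items()}

WAVE_DIR_NAMES = {
    1: "from_R_to_L",
    2: "from_B_to_T",
    3: "from_L_to_R",
    4: "from_T_to_B",
}


def sector_of_angle(angle_deg):
    """Map angles (deg) to sector ids 1-8.

    Sectors are half-open: the boundary angle centre+22.5 deg belongs to the
    next sector, so 22.5 deg falls in sector 2.
    """
    a = np.asarray(angle_deg, dtype=float) % 360.0
    sec = (np.floor(((a + 22.5) % 360.0) / 45.0).astype(int) % 8) + 1
    if np.isscalar(angle_deg):
        return int(sec)
    return sec


def sector_of(focus_pos, other_pos) -> int:
    """Sector of ``other_pos`` as seen from ``focus_pos``.

    Positions are (x, y) in a common planar frame with y pointing down
    (image convention); mm and px frames share the orientation so either
    may be used. Raises ``ValueError`` on coincident positions.
    """
    dx = float(other_pos[0]) - float(focus_pos[0])
    dy = float(other_pos[1]) - float(focus_pos[1])
    if dx == 0.0 and dy == 0.0:
        raise ValueError("coincident positions have no direction")
    angle = np.degrees(np.arctan2(dy, dx))
    return int(sector_of_angle(angle))


def sector_offset(sector: int, reference_sector: int) -> int:
    """Signed sector offset in {-3..4} (x45 deg gives -135..+180)."""
    d = (int(sector) - int(reference_sector)) % 8
    return d - 8 if d > 4 else d


def opposite_sector(sector: int) -> int:
    return (int(sector) - 1 + 4) % 8 + 1


def neighbors(agents: pd.DataFrame, focus_id: int, radius_mm: float) -> np.ndarray:
    """Agent ids strictly within ``radius_mm`` of the focus agent.

    ``agents`` must carry columns agent_id, x_mm, y_mm. Distances are
    computed in the nest plane (x, y); the bound is strict, so a neighbour
    at exactly the radius is excluded. The focus agent itself is excluded.
    """
    if radius_mm <= 0:
        raise ValueError("radius_mm must be positive")
    xy = agents[["x_mm", "y_mm"]].to_numpy(float)
    ids = agents["agent_id"].to_numpy()
    fmask = ids == focus_id
    if not fmask.any():
        raise KeyError(f"agent {focus_id} not in agent set")
    fxy = xy[fmask][0]
    d = np.hypot(xy[:, 0] - fxy[0], xy[:, 1] - fxy[1])
    return ids[(d < radius_mm) & ~fmask]


def pairwise_neighbor_ids(agents: pd.DataFrame, radius_mm: float) -> dict[int, np.ndarray]:
    """Neighbour lists for every agent (strict ``< radius_mm``)."""
    xy = agents[["x_mm", "y_mm"]].to_numpy(float)
    ids = agents["agent_id"].to_numpy()
    d = np.hypot(xy[:, None, 0] - xy[None, :, 0], xy[:, None, 1] - xy[None, :, 1])
    np.fill_diagonal(d, np.inf)
    return {int(ids[i]): ids[d[i] < radius_mm] for i in range(len(ids))}


def group_waves(incidents: pd.DataFrame, gap_frames: int) -> pd.DataFrame:
    """Assign wave ids by temporal clustering of incident onsets.

    Incidents whose t0 gap to the previous onset exceeds ``gap_frames``
    start a new wave. Returns a copy with a ``wave_id`` column (0-based).
    """
    out = incidents.copy()
    if out.empty:
        out["wave_id"] = pd.Series(dtype=int)
        return out
    order = np.argsort(out["t0"].to_numpy(), kind="stable")
    t0 = out["t0"].to_numpy()[order]
    new_wave = np.zeros(len(t0), dtype=int)
    new_wave[1:] = (np.diff(t0) > gap_frames).astype(int)
    wave_ids = np.cumsum(new_wave)
    col = np.empty(len(t0), dtype=int)
    col[order] = wave_ids
    out["wave_id"] = col
    return out


def assign_trigger(
    focus: pd.Series,
    candidates: pd.DataFrame,
    agents: pd.DataFrame,
    near_radius_mm: float = 40.0,
    window_frames: int = 5,
):
    """Pick the trigger neighbour of one focus incident.

    Candidates are incidents of other agents; qualifying ones lie strictly
    inside the near neighbourhood, belong to the same wave, and started
    1..``window_frames`` frames before the focus incident. Among them the
    spatially closest wins; ties break on earlier t0, then lower agent_id.

    Returns ``(trigger_id, dir_trig)`` or ``(None, None)`` when no
    candidate qualifies (the focus bee is then untriggered-active).
    """
    pos = agents.set_index("agent_id")[["x_mm", "y_mm"]]
    fxy = pos.loc[focus["agent_id"]].to_numpy(float)
    cand = candidates[candidates["agent_id"] != focus["agent_id"]]
    dt = focus["t0"] - cand["t0"]
    cand = cand[(dt >= 1) & (dt <= window_frames)]
    if "wave_id" in focus.index and "wave_id" in cand.columns:
        cand = cand[cand["wave_id"] == focus["wave_id"]]
    if cand.empty:
        return None, None
    cxy = pos.loc[cand["agent_id"]].to_numpy(float)
    dist = np.hypot(cxy[:, 0] - fxy[0], cxy[:, 1] - fxy[1])
    ok = dist < near_radius_mm
    if not ok.any():
        return None, None
    cand = cand.iloc[np.flatnonzero(ok)].copy()
    cand["_dist"] = dist[ok]
    cand = cand.sort_values(["_dist", "t0", "agent_id"], kind="stable")
    best = cand.iloc[0]
    trig_id = int(best["agent_id"])
    d_trig = sector_of(fxy, pos.loc[trig_id].to_numpy(float))
    return trig_id, d_trig


def assign_all_triggers(
    incidents: pd.DataFrame,
    agents: pd.DataFrame,
    near_radius_mm: float = 40.0,
    window_frames: int = 5,
) -> pd.DataFrame:
    """Vectorised trigger assignment for a whole incident table.

    Adds ``trigger_id`` (nullable int), ``dir_trig`` (nullable int) and
    ``role`` ("focus" or "untriggered-active") columns. Deterministic and
    independent of row order (distance, then t0, then agent_id tie-break).
    """
    out = incidents.copy()
    pos = agents.set_index("agent_id")[["x_mm", "y_mm"]]
    xy = pos.loc[out["agent_id"]].to_numpy(float)
    t0 = out["t0"].to_numpy()
    wave = out["wave_id"].to_numpy() if "wave_id" in out else np.zeros(len(out), int)
    aid = out["agent_id"].to_numpy()

    trig_id = np.full(len(out), -1)
    dir_trig = np.full(len(out), -1)
    for i in range(len(out)):
        dt = t0[i] - t0
        mask = (dt >= 1) & (dt <= window_frames) & (wave == wave[i]) & (aid != aid[i])
        if not mask.any():
            continue
        j = np.flatnonzero(mask)
        dist = np.hypot(xy[j, 0] - xy[i, 0], xy[j, 1] - xy[i, 1])
        near = dist < near_radius_mm
        if not near.any():
            continue
        j, dist = j[near], dist[near]
        order = np.lexsort((aid[j], t0[j], dist))
        k = j[order[0]]
        trig_id[i] = aid[k]
        dir_trig[i] = sector_of(xy[i], xy[k])

    out["trigger_id"] = pd.array(
        np.where(trig_id >= 0, trig_id, 0), dtype="Int64"
    )
    out.loc[trig_id < 0, "trigger_id"] = pd.NA
    out["dir_trig"] = pd.array(np.where(dir_trig >= 0, dir_trig, 0), dtype="Int64")
    out.loc[dir_trig < 0, "dir_trig"] = pd.NA
    out["role"] = np.where(trig_id >= 0, "focus", "untriggered-active")
    return out


def classify_wave_direction(
    incidents: pd.DataFrame,
    agents: pd.DataFrame,
    min_incidents: int = 10,
    override: int | None = None,
):
    """Label a wave with one of the 4 key directions from its onset field.

    Fits the plane t0 ~ a + b*x + c*y by least squares; the wave propagates
    along the t0 gradient (b, c), hence comes from the opposite angle,
    which is snapped to the nearest key direction. Returns the direction id
    (1-4) or ``None`` for degenerate fits (all onsets simultaneous or too
    few incidents), in which case the wave is flagged undefined.

    A manual ``override`` (1-4) is honoured unconditionally, preserving the
    visual-labelling workflow.
    """
    if override is not None:
        if override not in WAVE_DIR_SECTOR:
            raise ValueError("override must be a key direction 1-4")
        return override
    if len(incidents) < min_incidents:
        return None
    pos = agents.set_index("agent_id")[["x_mm", "y_mm"]]
    xy = pos.loc[incidents["agent_id"]].to_numpy(float)
    t0 = incidents["t0"].to_numpy(float)
    if np.ptp(t0) == 0:
        return None
    design = np.column_stack([np.ones(len(t0)), xy])
    coef, *_ = np.linalg.lstsq(design, t0, rcond=None)
    b, c = coef[1], coef[2]
    if b == 0 and c == 0:
        return None
    origin_angle = np.degrees(np.arctan2(-c, -b)) % 360.0
    best = min(
        WAVE_DIR_ANGLE,
        key=lambda d: min(
            abs(origin_angle - WAVE_DIR_ANGLE[d]),
            360 - abs(origin_angle - WAVE_DIR_ANGLE[d]),
        ),
    )
    return int(best)
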