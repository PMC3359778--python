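"""Model/Results interface tying the pipeline stages together.

:class:`ShimmeringModel` is built from per-agent motion traces plus agent
positions (from rendered or real video via :mod:`shimmerwave.motion`, or
directly from the simulator) and a :class:`~shimmerwave.config.PipelineConfig`.
Calling :meth:`ShimmeringModel.fit` runs incident detection, wave
grouping, trigger assignment, wave-direction labelling and the three
bucket-bridging analyses (linearity, continuity, graduality) plus the
time-course estimates, and returns a :class:`ShimmeringResults` carrying
every intermediate table, the headline estimates with uncertainties, and
a ``summary()`` report.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from . import detect as _detect
from . import graduality as _grad
from . import neighborhood as _nbh
from . import timecourse as _tc
from . import wavestats as _ws
from .config import PipelineConfig
from .motion import compute_traces, traces_to_wide
from .synthetic import AgentSet

__all__ = ["ShimmeringModel", "ShimmeringResults", "hallmarks_report"]


def hallmarks_report(
    participation_pct: float,
    focus_pct: float,
    weak_pct: float,
    mid_pct: float,
    strong_pct: float,
    linearity_pct: float,
    continuity_pct: float,
    graduality_pct: float,
) -> pd.DataFrame:
    """Chained bucket-bridging hallmark shares.

    Every argument is a percentage of its own reference population
    (surface bees -> shimmering-active bees -> focus bees -> criterion
    conformers); the report chains them by exact multiplication down to
    shares of all surface bees, e.g. 53.06% participation x 75.72% focus
    share = 40.18% of all surface bees.
    """
    of_active = focus_pct
    focus_of_surface = participation_pct * of_active / 100.0
    rows = [
        ("shimmering-active", "surface bees", participation_pct, participation_pct),
        ("focus bees", "active bees", focus_pct, focus_of_surface),
        ("weak strength", "focus bees", weak_pct, focus_of_surface * weak_pct / 100.0),
        ("mid strength", "focus bees", mid_pct, focus_of_surface * mid_pct / 100.0),
        ("strong strength", "focus bees", strong_pct, focus_of_surface * strong_pct / 100.0),
        ("linearity", "focus incidents", linearity_pct, focus_of_surface * linearity_pct / 100.0),
        ("continuity", "focus incidents", continuity_pct, focus_of_surface * continuity_pct / 100.0),
        ("graduality", "focus incidents", graduality_pct, focus_of_surface * graduality_pct / 100.0),
    ]
    return pd.DataFrame(
        rows, columns=["group", "reference", "pct_of_reference", "pct_of_surface"]
    )


class ShimmeringModel:
    """Single-agent shimmering-wave analysis model.

    Parameters
    ----------
    traces : DataFrame
        Wide frames x agent_id table of rel_xymov motion strength (or a
        long (frame, agent_id, rel_xymov) table, which is pivoted).
    agents : DataFrame or AgentSet
        Agent positions with columns agent_id, x_mm, y_mm.
    config : PipelineConfig, optional
    truth : SimulationTruth, optional
        Attached for parameter-recovery diagnostics; never consulted by
        the fit itself.
    wave_dir_overrides : dict, optional
        Manual wave-direction labels {wave_id: 1-4} taking precedence
        over the automatic plane-fit labelling.
    """

    def __init__(
        self,
        traces: pd.DataFrame,
        agents,
        config: PipelineConfig | None = None,
        truth=None,
        wave_dir_overrides: dict[int, int] | None = None,
    ) -> None:
        if isinstance(agents, AgentSet):
            agents = agents.table
        if {"frame", "agent_id", "rel_xymov"} <= set(traces.columns):
            traces = traces_to_wide(traces)
        self.traces = traces
        self.agents = agents.reset_index(drop=True)
        self.config = config or PipelineConfig()
        self.truth = truth
        self.wave_dir_overrides = wave_dir_overrides or {}

    # -- constructors --------------------------------------------------

    @classmethod
    def from_frames(
        cls,
        stack: np.ndarray,
        tracks: pd.DataFrame,
        config: PipelineConfig | None = None,
        **kw,
    ) -> "ShimmeringModel":
        """Build from a grayscale frame stack and a track table.

        Runs the frame-differencing motion metric; agent positions are
        the per-agent median tracked positions (mm).
        """
        config = config or PipelineConfig()
        long = compute_traces(stack, tracks, roi_px=config.roi_px)
        agents = (
            tracks.groupby("agent_id")[["x_mm", "y_mm"]].median().reset_index()
        )
        return cls(traces_to_wide(long), agents, config, **kw)

    @classmethod
    def from_simulation(
        cls,
        agents: AgentSet,
        strengths: pd.DataFrame,
        config: PipelineConfig | None = None,
        truth=None,
        **kw,
    ) -> "ShimmeringModel":
        """Build directly from simulated strength traces."""
        return cls(strengths, agents, config, truth=truth, **kw)

    # -- fitting -------------------------------------------------------

    def fit(self) -> "ShimmeringResults":
        cfg = self.config
        incidents = _detect.detect_all(
            self.traces,
            baseline=None,
            threshold=cfg.detect_threshold,
            min_run_frames=cfg.min_run_frames,
            merge_frames=cfg.refractory_frames,
            quiescent_window=cfg.quiescent_window,
            fallback_baseline=cfg.baseline_rel,
        )
        incidents["c_ws"] = _detect.categorize_ws(
            incidents["peak_rel"].to_numpy(), cfg.cws_bounds_rel
        ) if len(incidents) else pd.Series(dtype=int)
        incidents = _nbh.group_waves(incidents, cfg.refractory_frames)
        incidents = _nbh.assign_all_triggers(
            incidents,
            self.agents,
            near_radius_mm=cfg.near_radius_mm,
            window_frames=cfg.trigger_window_frames,
        )
        waves = self._label_waves(incidents)
        incidents = incidents.merge(
            waves[["wave_id", "dir_wav"]], on="wave_id", how="left"
        )
        return ShimmeringResults(model=self, incidents=incidents, waves=waves)

    def _label_waves(self, incidents: pd.DataFrame) -> pd.DataFrame:
        rows = []
        for wave_id, grp in incidents.groupby("wave_id"):
            override = self.wave_dir_overrides.get(int(wave_id))
            d = _nbh.classify_wave_direction(grp, self.agents, override=override)
            rows.append(
                {
                    "wave_id": int(wave_id),
                    "dir_wav": d,
                    "n_incidents": len(grp),
                    "t0_first": int(grp["t0"].min()),
                    "t0_last": int(grp["t0"].max()),
                    "flagged_undefined": d is None,
                }
            )
        waves = pd.DataFrame(
            rows,
            columns=[
                "wave_id", "dir_wav", "n_incidents",
                "t0_first", "t0_last", "flagged_undefined",
            ],
        )
        waves["dir_wav"] = waves["dir_wav"].astype("Int64")
        return waves


@dataclass
class ShimmeringResults:
    """Fitted shimmering analysis.

    Lazily computes and caches the three bucket-bridging analyses and
    the time-course estimates on first access.
    """

    model: ShimmeringModel
    incidents: pd.DataFrame
    waves: pd.DataFrame
    _cache: dict = field(default_factory=dict, repr=False)

    # -- basic counts --------------------------------------------------

    @property
    def n_agents(self) -> int:
        return len(self.model.agents)

    @property
    def n_incidents(self) -> int:
        return len(self.incidents)

    @property
    def participation_pct(self) -> float:
        """Percent of agents with at least one wave incident."""
        if self.n_agents == 0:
            return float("nan")
        return 100.0 * self.incidents["agent_id"].nunique() / self.n_agents

    @property
    def focus_pct(self) -> float:
        """Percent of incidents whose agent was triggered (focus role)."""
        if self.n_incidents == 0:
            return float("nan")
        return 100.0 * (self.incidents["role"] == "focus").mean()

    def strength_shares(self, weak=(1, 1), mid=(2, 4), strong=(5, 8)) -> dict[str, float]:
        """Percent of focus incidents in weak / mid / strong c_ws bands."""
        fb = self.incidents[self.incidents["role"] == "focus"]
        if fb.empty:
            return {"weak": float("nan"), "mid": float("nan"), "strong": float("nan")}
        c = fb["c_ws"]
        return {
            "weak": 100.0 * c.between(*weak).mean(),
            "mid": 100.0 * c.between(*mid).mean(),
            "strong": 100.0 * c.between(*strong).mean(),
        }

    # -- analyses ------------------------------------------------------

    @property
    def linearity(self) -> _ws.LinearityResult:
        if "linearity" not in self._cache:
            self._cache["linearity"] = _ws.linearity_analysis(
                self.incidents, degree=self.model.config.poly_degree
            )
        return self._cache["linearity"]

    @property
    def continuity(self) -> _ws.ContinuityResult:
        if "continuity" not in self._cache:
            cfg = self.model.config
            self._cache["continuity"] = _ws.continuity_profile(
                self.incidents,
                self.model.agents,
                far_radius_mm=cfg.far_radius_mm,
                window_frames=cfg.continuity_window_frames,
            )
        return self._cache["continuity"]

    @property
    def graduality(self) -> _grad.GradualitySummary:
        if "graduality" not in self._cache:
            cfg = self.model.config
            self._cache["graduality"] = _grad.graduality_summary(
                self.incidents,
                self.model.agents,
                by=("c_ws",),
                far_radius_mm=cfg.far_radius_mm,
                window_frames=cfg.continuity_window_frames,
            )
        return self._cache["graduality"]

    @property
    def trigger_coupling(self) -> tuple[float, float]:
        """(r, k) of focus peak on trigger peak (near-neighbourhood)."""
        if "trigger_coupling" not in self._cache:
            self._cache["trigger_coupling"] = _grad.trigger_regression(self.incidents)
        return self._cache["trigger_coupling"]

    @property
    def ensembles(self) -> dict[int, dict[str, _tc.EnsembleCurve]]:
        if "ensembles" not in self._cache:
            cfg = self.model.config
            self._cache["ensembles"] = _tc.synchronize(
                self.model.traces,
                self.incidents,
                window_ms=cfg.ensemble_window_ms,
                fps=cfg.fps,
            )
        return self._cache["ensembles"]

    @property
    def transfer(self) -> dict[str, Any]:
        """Transfer time per c_ws stratum and pooled mean +- SE (ms)."""
        if "transfer" not in self._cache:
            cfg = self.model.config
            per = {}
            for c_ws, curves in self.ensembles.items():
                if "nb" in curves:
                    tt = _tc.transfer_time(
                        curves["fb"], curves["nb"], cfg.transfer_thresholds
                    )
                    if tt.reliable:
                        per[c_ws] = tt
            means = [tt.mean_ms for tt in per.values()]
            pooled = float(np.mean(means)) if means else float("nan")
            se = (
                float(np.std(means, ddof=1) / np.sqrt(len(means)))
                if len(means) > 1
                else 0.0
            )
            self._cache["transfer"] = {
                "per_stratum": per,
                "mean_ms": pooled,
                "se_ms": se,
                "n_strata": len(per),
            }
        return self._cache["transfer"]

    @property
    def mean_trigger_distance_mm(self) -> float:
        """Mean planar distance between focus bees and their triggers."""
        fb = self.incidents[
            (self.incidents["role"] == "focus") & self.incidents["trigger_id"].notna()
        ]
        if fb.empty:
            return float("nan")
        pos = self.model.agents.set_index("agent_id")[["x_mm", "y_mm"]]
        a = pos.loc[fb["agent_id"]].to_numpy(float)
        b = pos.loc[fb["trigger_id"].astype(int)].to_numpy(float)
        return float(np.hypot(*(a - b).T).mean())

    @property
    def speed(self) -> tuple[float, float]:
        """Propagation speed (m/s) of one bucket-bridging step, with SE."""
        tr = self.transfer
        if not np.isfinite(tr["mean_ms"]) or tr["mean_ms"] <= 0:
            return float("nan"), float("nan")
        return _tc.propagation_speed(
            self.mean_trigger_distance_mm, tr["mean_ms"], tr["se_ms"]
        )

    @property
    def repetition(self) -> tuple[float, float]:
        """(rate Hz, refractory ms) from inter-incident intervals."""
        return _detect.repetition_rate(self.incidents, fps=self.model.config.fps)

    @property
    def hallmarks(self) -> pd.DataFrame:
        shares = self.strength_shares()
        lin = self.linearity.estimate_B_mean if len(self.linearity.rel_n_fb) else float("nan")
        cont = self.continuity.excess_rate_pooled
        try:
            r_ds = self.graduality.r_ds_mean
            grad = 100.0 * r_ds**2 if np.isfinite(r_ds) else float("nan")
        except ValueError:
            grad = float("nan")
        return hallmarks_report(
            self.participation_pct,
            self.focus_pct,
            shares["weak"],
            shares["mid"],
            shares["strong"],
            lin,
            cont,
            grad,
        )

    # -- reporting -----------------------------------------------------

    def summary(self) -> str:
        """Plain-text summary of the fitted analysis."""
        cfg = self.model.config
        lines = [
            "Shimmering-wave bucket-bridging analysis",
            "=" * 56,
            f"agents: {self.n_agents}   frames: {len(self.model.traces)}   "
            f"incidents: {self.n_incidents}   waves: {len(self.waves)}",
            f"config hash: {cfg.hash()}",
            "-" * 56,
            f"participation: {self.participation_pct:.2f}% of agents",
            f"focus share:   {self.focus_pct:.2f}% of incidents",
        ]
        if len(self.linearity.rel_n_fb):
            lin = self.linearity
            coin = all(lin.coincidence.values())
            lines += [
                f"linearity estimate A: {lin.estimate_A_mean:.2f}%  "
                f"B: {lin.estimate_B_mean:.2f}%  coincidence: "
                f"{'100%' if coin else 'partial'}",
            ]
        cont = self.continuity
        if np.isfinite(cont.excess_rate_pooled):
            lines.append(f"continuity excess rate: {cont.excess_rate_pooled:.2f}%")
        try:
            g = self.graduality
            lines.append(
                f"graduality r_ds: {g.r_ds_mean:.4f}+-{g.r_ds_se:.4f}  "
                f"r_os: {g.r_os_mean:.4f}+-{g.r_os_se:.4f}  P={g.p_value:.4f}"
            )
        except ValueError:
            pass
        tr = self.transfer
        if np.isfinite(tr["mean_ms"]):
            sp, sp_se = self.speed
            lines += [
                f"transfer time: {tr['mean_ms']:.2f}+-{tr['se_ms']:.2f} ms "
                f"(n={tr['n_strata']} strata)",
                f"propagation speed: {sp:.3f}+-{sp_se:.3f} m/s "
                f"(mean step {self.mean_trigger_distance_mm:.1f} mm)",
            ]
        rate, refr = self.repetition
        if np.isfinite(rate):
            lines.append(
                f"repetition rate: {rate:.3f} Hz   refractory ~ {refr:.0f} ms"
            )
        return "\n".join(lines)

    def to_json_dict(self) -> dict:
        """Headline numbers as a JSON-serialisable dict."""
        shares = self.strength_shares()
        out = {
            "config_hash": self.model.config.hash(),
            "n_agents": self.n_agents,
            "n_incidents": self.n_incidents,
            "n_waves": len(self.waves),
            "participation_pct": self.participation_pct,
            "focus_pct": self.focus_pct,
            "strength_shares_pct": shares,
        }
        if len(self.linearity.rel_n_fb):
            out["linearity"] = {
                "estimate_A_pct": self.linearity.estimate_A_mean,
                "estimate_B_pct": self.linearity.estimate_B_mean,
                "coincidence": {str(k): bool(v) for k, v in self.linearity.coincidence.items()},
            }
        out["continuity_excess_pct"] = self.continuity.excess_rate_pooled
        try:
            g = self.graduality
            out["graduality"] = {
                "r_ds_mean": g.r_ds_mean,
                "r_os_mean": g.r_os_mean,
                "p_value": g.p_value,
            }
        except ValueError:
            pass
        tr = self.transfer
        out["transfer_ms"] = {"mean": tr["mean_ms"], "se": tr["se_ms"]}
        sp, sp_se = self.speed
        out["speed_m_per_s"] = {"mean": sp, "se": sp_se}
        rate, refr = self.repetition
        out["repetition_hz"] = rate
        out["refractory_ms_est"] = refr
        return out
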