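"""Pipeline configuration.

All physically meaningful defaults follow the recording geometry of the
original field setup: 60 fps black-and-white video, 0.30 mm per pixel,
a 60x60 px region of interest per bee, and near/far neighbourhood radii
of 40 mm and 100 mm around a focus bee.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

#: Divisor turning a raw ROI luminance-difference sum into rel_xymov units.
REL_NORM = 1.0e4

#: Quiescent rel_xymov level: ~3 grey levels per pixel over a 60x60 px ROI.
QUIESCENT_REL = 1.08


@dataclass(frozen=True)
class PipelineConfig:
    """Parameters shared by every pipeline stage.

    Attributes
    ----------
    fps : float
        Frame rate of the recording (frames per second).
    mm_per_px : float
        Metric scale of the image plane.
    roi_px : int
        Side length of the square motion-detection window around a bee.
    near_radius_mm, far_radius_mm : float
        Radii of the near and far neighbourhood discs around a focus bee.
        Distances are compared strictly (< radius).
    detect_threshold : float
        Supra-baseline excess, in rel_xymov units, that a trace must exceed
        to count as shimmering participation (raw-sum units: x 1e4).
    min_run_frames : int
        Number of consecutive supra-threshold frames required for a wave
        incident; excludes noise-triggered events.
    baseline_rel : float
        Fallback quiescent rel_xymov level when no quiescent window is
        declared for per-agent baselines.
    cws_bound_multiples : tuple of float
        Lower bounds of the eight wave-strength levels, as multiples of the
        baseline level. Strictly increasing; below the first bound is
        non-participation (c_ws = 0).
    trigger_window_frames : int
        Maximum age, in frames, of a near-neighbour incident that can act
        as the trigger of a focus bee.
    refractory_ms : float
        Minimum separation of two incidents of one agent; also the wave
        split gap for temporal wave grouping.
    continuity_window_frames : int
        Pre-t0 window within which far-neighbour activity counts towards
        the continuity and graduality statistics.
    ensemble_window_ms : (float, float)
        Relative time span of the synchronized ensemble curves, 0 at t0.
    transfer_thresholds : tuple of float
        rel_xymov levels at which focus/neighbour curve crossings are
        interpolated for the transfer-time estimate.
    poly_degree : int
        Degree of the polynomial fitted to the trigger-direction histogram
        when estimating the linearity fuzziness level.
    """

    fps: float = 60.0
    mm_per_px: float = 0.30
    roi_px: int = 60
    near_radius_mm: float = 40.0
    far_radius_mm: float = 100.0
    detect_threshold: float = 1.0
    min_run_frames: int = 5
    baseline_rel: float = QUIESCENT_REL
    quiescent_window: tuple[int, int] | None = None
    cws_bound_multiples: tuple[float, ...] = (1.5, 2.0, 3.0, 4.5, 6.5, 9.0, 12.0, 16.0)
    trigger_window_frames: int = 5
    refractory_ms: float = 800.0
    continuity_window_frames: int = 15
    ensemble_window_ms: tuple[float, float] = (-200.0, 600.0)
    transfer_thresholds: tuple[float, ...] = tuple(
        round(1.0 + 0.1 * i, 1) for i in range(14)
    )
    poly_degree: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fps", "mm_per_px", "roi_px", "near_radius_mm",
                     "far_radius_mm", "refractory_ms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.min_run_frames < 1 or self.trigger_window_frames < 1:
            raise ValueError("frame windows must be >= 1")
        bounds = self.cws_bound_multiples
        if len(bounds) != 8 or any(b <= a for a, b in zip(bounds, bounds[1:])):
            raise ValueError("cws_bound_multiples must be 8 strictly increasing values")

    @property
    def frame_interval_ms(self) -> float:
        """Duration of one frame in ms (16.67 ms at 60 fps)."""
        return 1000.0 / self.fps

    @property
    def refractory_frames(self) -> int:
        return int(round(self.refractory_ms / self.frame_interval_ms))

    @property
    def cws_bounds_rel(self) -> tuple[float, ...]:
        """Absolute level boundaries in rel_xymov units."""
        return tuple(m * self.baseline_rel for m in self.cws_bound_multiples)

    # -- serialisation -------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("cws_bound_multiples", "transfer_thresholds"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        for key in ("quiescent_window", "ensemble_window_ms"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_jsonable(self.to_dict()), fh, sort_keys=False)

    def hash(self) -> str:
        """Stable short hash identifying this configuration."""
        blob = json.dumps(_jsonable(self.to_dict()), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (tuple, list)):
        return [_jsonable(v) for v in obj]
    return obj
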