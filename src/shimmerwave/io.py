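"""File I/O: frame sequences, track/incident tables, result bundles.

Frame stacks are numbered PNG/TIFF sequences; tabular data is CSV;
results are JSON. Every result file is stamped with the hash of the
configuration that produced it.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .config import PipelineConfig

__all__ = [
    "write_frames",
    "read_frames",
    "write_table",
    "read_table",
    "write_results",
    "read_results",
]

TRACK_COLUMNS = ["frame", "agent_id", "x_px", "y_px", "x_mm", "y_mm", "z_mm"]


def write_frames(stack: np.ndarray, directory: str | Path, fmt: str = "png") -> list[Path]:
    """Write a (n, H, W) uint8 stack as a numbered image sequence."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, frame in enumerate(stack):
        p = directory / f"frame_{i:06d}.{fmt}"
        iio.imwrite(p, frame)
        paths.append(p)
    return paths


def read_frames(directory: str | Path, pattern: str = "frame_*.png") -> np.ndarray:
    """Read a numbered image sequence back into a (n, H, W) stack."""
    paths = sorted(Path(directory).glob(pattern))
    if not paths:
        raise FileNotFoundError(f"no frames matching {pattern} in {directory}")
    return np.stack([iio.imread(p) for p in paths])


def write_table(df: pd.DataFrame, path: str | Path, config: PipelineConfig | None = None) -> None:
    """Write a CSV table, optionally stamped with the config hash."""
    with open(path, "w") as fh:
        if config is not None:
            fh.write(f"# config_hash: {config.hash()}\n")
        df.to_csv(fh, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def _clean(obj):
    if isinstance(obj, dict):
        return {str(k): _clean(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_clean(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return f if np.isfinite(f) else None
    if isinstance(obj, np.ndarray):
        return _clean(obj.tolist())
    return obj


def write_results(results: dict, path: str | Path, config: PipelineConfig | None = None) -> None:
    """Write a results dict as JSON, stamped with the config hash."""
    payload = _clean(dict(results))
    if config is not None:
        payload.setdefault("config_hash", config.hash())
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=False)
        fh.write("\n")


def read_results(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
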