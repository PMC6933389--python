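"""File formats: multi-page TIFF movies/maps, 2-column breath CSV, JSON
sidecars, YAML configs."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .respiration import BreathTrace

__all__ = [
    "save_movie",
    "load_movie",
    "save_map",
    "load_map",
    "save_breath",
    "load_breath",
    "save_json",
    "load_json",
    "save_yaml",
    "load_yaml",
]


def save_movie(path: str | Path, movie: np.ndarray) -> None:
    """Write a T x H x W movie as 16-bit multi-page TIFF (values clipped and
    rounded to the uint16 range)."""
    m = np.clip(np.rint(np.asarray(movie)), 0, np.iinfo(np.uint16).max)
    tifffile.imwrite(str(path), m.astype(np.uint16))


def load_movie(path: str | Path) -> np.ndarray:
    m = tifffile.imread(str(path))
    if m.ndim == 2:
        m = m[None]
    return m.astype(np.float32)


def save_map(path: str | Path, values: np.ndarray) -> None:
    """Write an activity map as 32-bit float TIFF."""
    tifffile.imwrite(str(path), np.asarray(values, dtype=np.float32))


def load_map(path: str | Path) -> np.ndarray:
    return tifffile.imread(str(path)).astype(np.float32)


def save_breath(path: str | Path, trace: BreathTrace) -> None:
    pd.DataFrame(
        {"time_s": trace.times_s, "value": trace.samples}
    ).to_csv(path, index=False)


def load_breath(path: str | Path) -> BreathTrace:
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy()
    if t.size < 2:
        raise ValueError("breath CSV needs at least 2 samples")
    rate = 1.0 / float(np.median(np.diff(t)))
    return BreathTrace(samples=df["value"].to_numpy(), sample_rate_hz=rate)


class _NumpyEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return super().default(o)


def save_json(path: str | Path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, cls=_NumpyEncoder) + "\n")


def load_json(path: str | Path):
    return json.loads(Path(path).read_text())


def save_yaml(path: str | Path, obj) -> None:
    Path(path).write_text(yaml.safe_dump(obj, sort_keys=False))


def load_yaml(path: str | Path):
    return yaml.safe_load(Path(path).read_text())
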