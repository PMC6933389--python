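"""Trial-averaged ΔF/F0 activity maps.

Trials of the same stimulus are aligned on their respiration anchors (first
inhalation onset at/after stimulus onset), the raw bleach-corrected
intensities are averaged frame-wise across trials, and the averaged stack is
reduced to one map: the response image is the mean of 200 frames (1.6 s at
125 Hz) from the anchor, the baseline image the mean of 125 frames (1.0 s)
taken 1.4-0.4 s before the anchor, and the map is (response - baseline) /
baseline per pixel. Windows are half-open, so the frame counts equal
round(seconds x rate) exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .protocol import seconds_to_frames
from .respiration import BreathTrace

__all__ = [
    "Trial",
    "TrialSet",
    "ActivityMap",
    "average_aligned_trials",
    "compute_activity_map",
    "map_summary",
]

RESPONSE_S = 1.6
BASELINE_FROM_S = 1.4
BASELINE_TO_S = 0.4
BASELINE_FLOOR_FRACTION = 0.01  # of the movie's global median


@dataclass
class Trial:
    """One recorded (or simulated) presentation: bleach-corrected movie,
    breathing trace, stimulus identity and the computed alignment anchor."""

    movie: np.ndarray  # T x H x W
    frame_rate_hz: float
    breath: BreathTrace
    odorant: str
    concentration_pct: float
    stimulus_onset_s: float
    anchor_frame: int | None = None
    trial_id: str = ""


@dataclass
class TrialSet:
    """Trials sharing odorant and concentration (block-noise-excluded trials
    must already be removed)."""

    trials: list[Trial] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.trials:
            t0 = self.trials[0]
            for t in self.trials[1:]:
                if t.movie.shape[1:] != t0.movie.shape[1:]:
                    raise ValueError("trials differ in frame shape")
                if t.frame_rate_hz != t0.frame_rate_hz:
                    raise ValueError("trials differ in frame rate")
                if (t.odorant, t.concentration_pct) != (t0.odorant, t0.concentration_pct):
                    raise ValueError("trials differ in stimulus")


@dataclass
class ActivityMap:
    """ΔF/F0 image with provenance."""

    values: np.ndarray  # H x W, dimensionless
    odorant: str
    concentration_pct: float
    n_trials: int
    anchor_frame: int
    response_window_frames: int
    baseline_window: tuple[float, float]  # seconds before anchor (from, to)
    view: str = "dorsal"
    flipped: bool = False
    floored_pixels: np.ndarray | None = None  # mask of baseline-floor pixels


def average_aligned_trials(trial_set: TrialSet) -> tuple[np.ndarray, int]:
    """Average the raw aligned movies of a trial set.

    Each trial's frame axis is shifted so the anchors coincide; only the frame
    range covered by every trial is kept, and intensities are averaged
    pixel-wise (raw averaging precedes any ΔF/F0 computation). Returns the
    averaged movie and the anchor frame index within it. With one trial this
    is a pure shift; trials whose anchors differ by d frames shorten the
    output by d frames.
    """
    trials = trial_set.trials
    if not trials:
        raise ValueError("empty trial set")
    for t in trials:
        if t.anchor_frame is None:
            raise ValueError(f"trial {t.trial_id!r} has no alignment anchor")
    pre = min(t.anchor_frame for t in trials)
    post = min(t.movie.shape[0] - t.anchor_frame for t in trials)
    if pre < 0 or post <= 0:
        raise ValueError("aligned trials have no overlapping frame range")
    stack = np.stack(
        [t.movie[t.anchor_frame - pre: t.anchor_frame + post] for t in trials]
    )
    return stack.mean(axis=0), pre


def compute_activity_map(
    avg_movie: np.ndarray,
    anchor_frame: int,
    frame_rate_hz: float,
    response_s: float = RESPONSE_S,
    baseline_from_s: float = BASELINE_FROM_S,
    baseline_to_s: float = BASELINE_TO_S,
    odorant: str = "",
    concentration_pct: float = float("nan"),
    n_trials: int = 1,
    view: str = "dorsal",
) -> ActivityMap:
    """Reduce an anchor-aligned averaged movie to a ΔF/F0 map.

    Response window: ``[anchor, anchor + round(response_s * rate))`` (anchor
    frame inclusive). Baseline window: ``[anchor - round(baseline_from_s *
    rate), anchor - round(baseline_to_s * rate))``. At 125 Hz the defaults
    give exactly 200 response and 125 baseline frames. Pixels whose baseline
    falls below 1% of the movie's global median are set to 0 and flagged in
    ``floored_pixels``.
    """
    m = np.asarray(avg_movie, dtype=float)
    n = m.shape[0]
    r_len = seconds_to_frames(response_s, frame_rate_hz)
    b0 = anchor_frame - seconds_to_frames(baseline_from_s, frame_rate_hz)
    b1 = anchor_frame - seconds_to_frames(baseline_to_s, frame_rate_hz)
    r1 = anchor_frame + r_len
    if b0 < 0 or r1 > n:
        raise ValueError(
            f"windows out of range: baseline starts at frame {b0}, response "
            f"ends at frame {r1}, movie has {n} frames"
        )
    response = m[anchor_frame:r1].mean(axis=0)
    baseline = m[b0:b1].mean(axis=0)
    floor = BASELINE_FLOOR_FRACTION * float(np.median(m))
    bad = baseline < max(floor, np.finfo(float).tiny)
    values = np.zeros_like(baseline)
    np.divide(response - baseline, baseline, out=values, where=~bad)
    values[bad] = 0.0
    return ActivityMap(
        values=values,
        odorant=odorant,
        concentration_pct=concentration_pct,
        n_trials=n_trials,
        anchor_frame=anchor_frame,
        response_window_frames=r_len,
        baseline_window=(baseline_from_s, baseline_to_s),
        view=view,
        floored_pixels=bad,
    )


def map_summary(amap: ActivityMap, rois) -> pd.DataFrame:
    """Per-ROI mean ΔF/F0 table.

    ``rois`` is a GlomerulusSet (``symmetry.GlomerulusSet``) or any object
    with an iterable ``rois`` attribute of (id, mask) carriers. Empty ROIs
    are kept but flagged.
    """
    rows = []
    for roi in rois.rois:
        mask = roi.mask
        npix = int(mask.sum())
        rows.append(
            {
                "roi_id": roi.id,
                "n_pixels": npix,
                "mean_dff": float(amap.values[mask].mean()) if npix else float("nan"),
                "empty": npix == 0,
            }
        )
    return pd.DataFrame(rows, columns=["roi_id", "n_pixels", "mean_dff", "empty"])
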