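"""Inhalation-event detection and trial-alignment anchors.

The breathing signal (piezo element under the chest, sampled on the imaging
clock) is the timing reference for every trial: activity windows are anchored
to the first inhalation onset at or after stimulus onset. Inhalation onsets
are defined as upward zero-crossings of the low-passed, baseline-subtracted
signal; inhalation ends as the subsequent downward crossings. The piezo
polarity depends on mounting, so it is configurable with an automatic default.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import uniform_filter1d

from .protocol import round_half_away

__all__ = ["BreathTrace", "AlignmentAnchor", "detect_breath_events", "find_alignment_anchor"]


@dataclass
class BreathTrace:
    """Sampled respiration signal plus detected inhalation events.

    ``inhalation_onsets_s`` / ``inhalation_ends_s`` are empty until filled by
    :func:`detect_breath_events` (or by the synthetic generator's ground
    truth). Onsets are strictly increasing; each end lies between consecutive
    onsets.
    """

    samples: np.ndarray
    sample_rate_hz: float
    inhalation_onsets_s: np.ndarray = field(default_factory=lambda: np.empty(0))
    inhalation_ends_s: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sample_rate_hz

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.sample_rate_hz

    def with_events(self, onsets_s: np.ndarray, ends_s: np.ndarray) -> "BreathTrace":
        return replace(
            self,
            inhalation_onsets_s=np.asarray(onsets_s, dtype=float),
            inhalation_ends_s=np.asarray(ends_s, dtype=float),
        )


@dataclass(frozen=True)
class AlignmentAnchor:
    """First inhalation onset at or after stimulus onset, in time and frames."""

    trial_id: str
    anchor_time_s: float
    anchor_frame: int


def detect_breath_events(
    trace: BreathTrace,
    smoothing_s: float = 0.04,
    min_cycle_s: float = 0.15,
    baseline_window_s: float = 1.0,
    polarity: str = "auto",
) -> BreathTrace:
    """Detect inhalation onsets and ends from a raw breathing trace.

    Pipeline: boxcar low-pass of width ``smoothing_s``, subtraction of a
    rolling-mean baseline of width ``baseline_window_s``, optional sign flip
    (``polarity``: ``"pos"`` keeps the signal, ``"neg"`` flips it, ``"auto"``
    flips when more than half the detrended samples are positive — inhalation
    is assumed to be the shorter phase of the cycle), then upward
    zero-crossings as onsets with a refractory period of ``min_cycle_s``, and
    the next downward crossing after each onset as the inhalation end.

    Returns a copy of ``trace`` with the event lists filled in. Raises
    ``ValueError`` when no events are found (e.g. a constant trace).
    """
    x = np.asarray(trace.samples, dtype=float)
    fs = trace.sample_rate_hz
    n_smooth = max(1, round_half_away(smoothing_s * fs))
    n_base = max(n_smooth + 1, round_half_away(baseline_window_s * fs))
    y = uniform_filter1d(x, size=n_smooth, mode="nearest")
    y = y - uniform_filter1d(y, size=n_base, mode="nearest")

    if polarity not in ("auto", "pos", "neg"):
        raise ValueError(f"unknown polarity {polarity!r}")
    if polarity == "neg":
        y = -y
    elif polarity == "auto":
        if float(np.mean(y > 0)) > 0.5:
            y = -y

    pos = y > 0
    up = np.flatnonzero(~pos[:-1] & pos[1:]) + 1
    down = np.flatnonzero(pos[:-1] & ~pos[1:]) + 1
    if up.size == 0:
        raise ValueError("no inhalation events found in breathing trace")

    refractory = round_half_away(min_cycle_s * fs)
    onsets: list[int] = []
    for i in up:
        if not onsets or i - onsets[-1] >= refractory:
            onsets.append(int(i))
    onsets_idx = np.asarray(onsets)

    ends: list[float] = []
    kept_onsets: list[float] = []
    for k, i in enumerate(onsets_idx):
        limit = onsets_idx[k + 1] if k + 1 < onsets_idx.size else x.size
        after = down[(down > i) & (down < limit)]
        kept_onsets.append(i / fs)
        if after.size:
            ends.append(float(after[0]) / fs)
    return trace.with_events(np.asarray(kept_onsets), np.asarray(ends))


def find_alignment_anchor(
    trace: BreathTrace,
    stimulus_onset_s: float,
    frame_rate_hz: float,
    trial_id: str = "",
) -> AlignmentAnchor:
    """First inhalation onset at or after ``stimulus_onset_s`` (inclusive).

    The anchor frame is the onset time rounded (half away from zero) onto the
    imaging clock. Raises ``ValueError`` if the trace has no detected onsets
    after the stimulus.
    """
    onsets = np.asarray(trace.inhalation_onsets_s, dtype=float)
    if onsets.size == 0:
        raise ValueError("breath events not detected; run detect_breath_events first")
    after = onsets[onsets >= stimulus_onset_s]
    if after.size == 0:
        raise ValueError(
            f"no inhalation onset at or after stimulus onset {stimulus_onset_s:.3f} s"
        )
    t = float(after[0])
    return AlignmentAnchor(
        trial_id=trial_id,
        anchor_time_s=t,
        anchor_frame=round_half_away(t * frame_rate_hz),
    )
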