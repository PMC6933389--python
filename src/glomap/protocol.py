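"""Acquisition-protocol arithmetic.

Small, exact conversions that tie the recording protocol together: frame
accounting at a given frame rate, the flow-dilution rule for nominal odorant
concentrations, and the prism-window geometry of the medial-view preparation.
"""

from __future__ import annotations

import math

__all__ = [
    "seconds_to_frames",
    "frames_to_seconds",
    "nominal_concentration_pct",
    "prism_top_above_surface_mm",
    "round_half_away",
]


def round_half_away(x: float) -> int:
    """Round with halves away from zero (not banker's rounding)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def seconds_to_frames(seconds: float, frame_rate_hz: float) -> int:
    """Number of frames spanning ``seconds`` at ``frame_rate_hz``.

    13 s at 125 Hz gives 1,625 frames; a 1.6 s response window gives 200
    frames and a 1.0 s baseline window gives 125 frames.
    """
    if frame_rate_hz <= 0:
        raise ValueError("frame_rate_hz must be positive")
    return round_half_away(seconds * frame_rate_hz)


def frames_to_seconds(n_frames: int, frame_rate_hz: float) -> float:
    if frame_rate_hz <= 0:
        raise ValueError("frame_rate_hz must be positive")
    return n_frames / frame_rate_hz


def nominal_concentration_pct(liquid_dilution_pct: float, flow_dilution: float = 5.0) -> float:
    """Nominal odorant concentration after flow dilution.

    Odorant vapor from a liquid dilution is mixed 1:``flow_dilution`` with
    carrier air, so a 1% liquid dilution presented with 1:5 flow dilution is
    reported as 0.2% nominal.
    """
    if flow_dilution <= 0:
        raise ValueError("flow_dilution must be positive")
    return liquid_dilution_pct / flow_dilution


def prism_top_above_surface_mm(
    prism_path_mm: float = 1.5, focal_plane_offset_mm: float = 1.0
) -> float:
    """Height of the prism top above the dorsal bulb surface.

    The focal plane for the medial wall sits ``focal_plane_offset_mm`` below
    the dorsal focal plane because of the in-prism light path of
    ``prism_path_mm``; the prism top therefore protrudes by the difference
    (0.5 mm for a 1.5 mm prism and a 1 mm focal offset).
    """
    return prism_path_mm - focal_plane_offset_mm
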