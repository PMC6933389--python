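"""Ground-truth-annotated synthetic trials for the glomerular-imaging pipeline.

No imaging data are deposited with the study this pipeline targets, so every
downstream stage is exercised on a forward model with known ground truth:

* two mirror-related glomerular maps (Gaussian blobs; the medial map is the
  dorsal map reflected across the horizontal image axis, i.e. with the
  dorso-ventral axis inverted as seen through the mirror prism, and shifted
  along the anterior-posterior axis by the prism placement offset),
* a biphasic piezo-like breathing trace with known inhalation landmarks,
* a 2-s odor pulse whose command onset is synchronized to the end of an
  inhalation (never mid-inhalation), after >= 4 s of prestimulus baseline,
* breathing-coupled calcium transients with a GCaMP6f-like double-exponential
  kernel, triggered at each inhalation onset during the odor pulse,
* mono-exponential photobleaching (optionally spatially heterogeneous per
  quadrant) applied multiplicatively, and additive Gaussian sensor noise.

Amplitude convention: a glomerulus' tuning amplitude is defined as the
windowed ΔF/F0 it produces at the blob center over the standard response
window (1.6 s from the first post-stimulus inhalation onset). The temporal
response built from the sniff-triggered kernels is normalized to unit mean
over that window, so amplitude recovery downstream is independent of the
kernel shape chosen here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.ndimage import zoom

from .protocol import seconds_to_frames
from .respiration import BreathTrace

__all__ = [
    "Glomerulus",
    "MapSpec",
    "AcquisitionSpec",
    "BreathSpec",
    "StimulusSpec",
    "GroundTruth",
    "generate_map_pair",
    "generate_breath_trace",
    "schedule_stimulus",
    "render_trial",
    "render_activity_map",
    "simulate_trial_set",
    "calcium_kernel",
]

# GCaMP6f-like kernel time constants (s): fast rise, sub-second decay.
KERNEL_RISE_S = 0.05
KERNEL_DECAY_S = 0.6
RESPONSE_WINDOW_S = 1.6


@dataclass(frozen=True)
class Glomerulus:
    """One Gaussian-blob glomerulus: center (px), effective radius (Gaussian
    sigma, px; includes optical blur), and per-odorant ΔF/F0 tuning."""

    center_x_px: float
    center_y_px: float
    radius_px: float
    tuning: dict[str, float]

    def __post_init__(self) -> None:
        if self.radius_px <= 0:
            raise ValueError("radius_px must be positive")
        if any(a < 0 for a in self.tuning.values()):
            raise ValueError("tuning amplitudes must be non-negative")


@dataclass(frozen=True)
class MapSpec:
    """A glomerular map layout for one view (dorsal, or medial through the
    prism). ``flip_applied`` records whether the medial view is rendered
    dorso-ventrally inverted, as the mirror prism shows it; ``ap_offset_px``
    is the prism-placement shift along the anterior-posterior (column) axis."""

    glomeruli: tuple[Glomerulus, ...]
    view: str = "dorsal"
    ap_offset_px: int = 0
    flip_applied: bool = False
    frame_shape: tuple[int, int] = (128, 128)

    def __post_init__(self) -> None:
        if self.view not in ("dorsal", "medial"):
            raise ValueError(f"view must be 'dorsal' or 'medial', got {self.view!r}")
        h, w = self.frame_shape
        for g in self.glomeruli:
            if not (0 <= g.center_x_px < w and 0 <= g.center_y_px < h):
                raise ValueError(
                    f"glomerulus center ({g.center_x_px}, {g.center_y_px}) "
                    f"outside {h}x{w} frame"
                )


@dataclass(frozen=True)
class AcquisitionSpec:
    """Camera and photophysics parameters for one trial.

    Defaults follow the widefield protocol: 13 s at 125 Hz (1,625 frames),
    128x128 px over a 1.75x1.75 mm^2 field of view. ``bleach_fraction`` is the
    fraction of initial intensity lost at t -> inf; ``quadrant_tau_scale``
    optionally makes bleaching spatially heterogeneous (one multiplicative tau
    factor per image quadrant, row-major)."""

    frame_rate_hz: float = 125.0
    n_frames: int = 1625
    frame_shape: tuple[int, int] = (128, 128)
    pixel_size_um: float = 1750.0 / 128.0
    bleach_tau_s: float = 5.0
    bleach_fraction: float = 0.0
    noise_sd: float = 0.0
    base_level: float = 1000.0
    quadrant_tau_scale: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_rate_hz <= 0 or self.n_frames <= 0:
            raise ValueError("frame_rate_hz and n_frames must be positive")
        if not (0 <= self.bleach_fraction < 1):
            raise ValueError("bleach_fraction must lie in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate_hz


@dataclass(frozen=True)
class BreathSpec:
    """Breathing-rhythm parameters: cycle rate, inhalation duty fraction,
    per-cycle period jitter, waveform amplitude, and additive trace noise."""

    rate_hz: float = 2.0
    duty_inhale: float = 0.4
    jitter_sd_s: float = 0.02
    amplitude: float = 1.0
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rate_hz <= 0 or self.amplitude <= 0:
            raise ValueError("rate_hz and amplitude must be positive")
        if not (0 < self.duty_inhale < 1):
            raise ValueError("duty_inhale must lie in (0, 1)")
        if self.jitter_sd_s < 0 or self.noise_sd < 0:
            raise ValueError("jitter_sd_s and noise_sd must be non-negative")


@dataclass(frozen=True)
class StimulusSpec:
    """One odor presentation: 2-s pulse, >= 4 s prestimulus baseline, onset
    deferred to the first inhalation end at/after the requested time.

    ``saturation_c50_pct``: optional half-saturation nominal concentration;
    when set, effective amplitudes scale by c/(c + c50) (when ``None``,
    amplitudes equal the MapSpec tuning exactly)."""

    odorant: str
    nominal_concentration_pct: float = 0.2
    requested_onset_s: float = 5.0
    duration_s: float = 2.0
    min_prestimulus_s: float = 4.0
    saturation_c50_pct: float | None = None

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")

    def amplitude_scale(self) -> float:
        if self.saturation_c50_pct is None:
            return 1.0
        c = self.nominal_concentration_pct
        return c / (c + self.saturation_c50_pct)


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    odorant: str
    concentration_pct: float
    amplitudes: list[float]  # effective ΔF/F0 per glomerulus, this odorant
    centers_px: list[tuple[float, float]]  # (x, y) per glomerulus, this view
    pair_ids: list[int]  # homologous identity shared across views
    stimulus_onset_s: float
    anchor_time_s: float
    anchor_frame: int
    inhalation_onsets_s: list[float]
    inhalation_ends_s: list[float]
    bleach_fraction: float
    bleach_tau_s_blocks: list[list[float]]  # per 4x4-quadrant-resolved block grid
    ap_offset_px: int
    view: str

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        d = dict(d)
        d["centers_px"] = [tuple(c) for c in d["centers_px"]]
        return cls(**d)


# ---------------------------------------------------------------------------
# map generation


def generate_map_pair(
    n_glomeruli: int,
    odorant_panel: Sequence[str],
    chemotopy_axis: tuple[float, float] = (1.0, 0.0),
    seed: int = 0,
    frame_shape: tuple[int, int] = (128, 128),
    ap_offset_px: int = 8,
    radius_px: float = 5.0,
    peak_amplitude: float = 0.05,
    tuning_width: float = 1.0,
    min_separation_factor: float = 3.0,
    max_tries: int = 2000,
) -> tuple[MapSpec, MapSpec]:
    """Generate mirror-related dorsal and medial map specs with shared tuning.

    Glomeruli are placed uniformly at random (rejection sampling keeps centers
    ``min_separation_factor * radius_px`` apart and inside the frame in both
    views after the anterior-posterior offset). Tuning follows a chemotopic
    rule: glomeruli are ranked by their projection onto ``chemotopy_axis``
    (an (x, y) unit vector) and each odorant of the ordered panel peaks at a
    rank that moves monotonically with panel position, with Gaussian falloff
    of width ``tuning_width`` ranks; the most-sensitive glomerulus therefore
    drifts monotonically along the axis, in both views.

    The medial spec is the dorsal spec reflected about the horizontal image
    axis (center (x, y) -> (x + ap_offset_px, H-1-y)) with identical tuning.
    Raises ``RuntimeError`` when placement fails (overcrowded frame).
    """
    if n_glomeruli < 1:
        raise ValueError("n_glomeruli must be >= 1")
    if not odorant_panel:
        raise ValueError("odorant_panel must be non-empty")
    rng = np.random.default_rng(seed)
    h, w = frame_shape
    margin = 2.0 * radius_px
    lo_x = margin + max(0, -ap_offset_px)
    hi_x = w - 1 - margin - max(0, ap_offset_px)
    lo_y, hi_y = margin, h - 1 - margin
    if lo_x >= hi_x or lo_y >= hi_y:
        raise RuntimeError("frame too small for requested radius/offset")

    centers: list[tuple[float, float]] = []
    tries = 0
    while len(centers) < n_glomeruli:
        if tries >= max_tries:
            raise RuntimeError(
                f"placed only {len(centers)}/{n_glomeruli} glomeruli after "
                f"{max_tries} tries; frame overcrowded"
            )
        tries += 1
        x = rng.uniform(lo_x, hi_x)
        y = rng.uniform(lo_y, hi_y)
        if all(
            (x - cx) ** 2 + (y - cy) ** 2 >= (min_separation_factor * radius_px) ** 2
            for cx, cy in centers
        ):
            centers.append((x, y))

    ax, ay = chemotopy_axis
    norm = float(np.hypot(ax, ay))
    if norm == 0:
        raise ValueError("chemotopy_axis must be nonzero")
    ax, ay = ax / norm, ay / norm
    proj = np.array([cx * ax + cy * ay for cx, cy in centers])
    rank_of = np.empty(n_glomeruli, dtype=int)
    rank_of[np.argsort(proj)] = np.arange(n_glomeruli)

    m = len(odorant_panel)
    peak_ranks = [
        round(j * (n_glomeruli - 1) / max(m - 1, 1)) for j in range(m)
    ]
    glomeruli = []
    for i, (cx, cy) in enumerate(centers):
        tuning = {
            od: float(
                peak_amplitude
                * np.exp(-((rank_of[i] - pr) ** 2) / (2.0 * tuning_width**2))
            )
            for od, pr in zip(odorant_panel, peak_ranks)
        }
        glomeruli.append(Glomerulus(cx, cy, radius_px, tuning))

    dorsal = MapSpec(tuple(glomeruli), view="dorsal", ap_offset_px=0,
                     flip_applied=False, frame_shape=frame_shape)
    medial = MapSpec(
        tuple(
            Glomerulus(g.center_x_px + ap_offset_px, h - 1 - g.center_y_px,
                       g.radius_px, g.tuning)
            for g in glomeruli
        ),
        view="medial",
        ap_offset_px=ap_offset_px,
        flip_applied=True,
        frame_shape=frame_shape,
    )
    return dorsal, medial


# ---------------------------------------------------------------------------
# breathing


def generate_breath_trace(
    spec: BreathSpec,
    duration_s: float,
    sample_rate_hz: float = 125.0,
) -> tuple[BreathTrace, np.ndarray, np.ndarray]:
    """Sample a piezo-like breathing trace with known phase landmarks.

    The waveform is biphasic per cycle: a positive half-sine of amplitude
    ``amplitude`` over the inhalation (``duty_inhale`` of the period) and a
    negative half-sine over the exhalation whose amplitude is scaled so the
    two lobes have equal area. Each cycle therefore integrates to zero and
    the upward/downward zero-crossings fall exactly at the ground-truth
    inhalation onsets/ends, surviving rolling-baseline subtraction in the
    detector. Cycle periods are jittered by a truncated Gaussian of SD
    ``jitter_sd_s``; Gaussian noise of SD ``noise_sd`` is added per sample.

    Returns ``(trace, true_onsets_s, true_ends_s)``; the trace's own event
    lists are left empty for the detector to fill.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if spec.rate_hz * duration_s < 2:
        raise ValueError("trial must cover at least 2 breathing cycles")
    rng = np.random.default_rng(spec.seed)
    period = 1.0 / spec.rate_hz

    onsets, ends = [], []
    t0 = 0.0
    while t0 < duration_s:
        p = period + (rng.normal(0.0, spec.jitter_sd_s) if spec.jitter_sd_s else 0.0)
        p = max(p, 0.5 * period)
        onsets.append(t0)
        ends.append(t0 + spec.duty_inhale * p)
        t0 += p
    onsets_arr = np.asarray(onsets)
    ends_arr = np.asarray(ends)

    t = np.arange(int(round(duration_s * sample_rate_hz))) / sample_rate_hz
    x = np.zeros_like(t)
    for k, on in enumerate(onsets_arr):
        end = ends_arr[k]
        nxt = onsets_arr[k + 1] if k + 1 < onsets_arr.size else on + period
        inh = (t >= on) & (t < end)
        exh = (t >= end) & (t < nxt)
        x[inh] = spec.amplitude * np.sin(np.pi * (t[inh] - on) / (end - on))
        # exhalation lobe scaled for equal area -> zero mean per cycle
        exh_amp = spec.amplitude * (end - on) / max(nxt - end, 1e-9)
        x[exh] = -exh_amp * np.sin(np.pi * (t[exh] - end) / (nxt - end))
    if spec.noise_sd:
        x = x + rng.normal(0.0, spec.noise_sd, size=x.shape)

    keep = onsets_arr < duration_s
    trace = BreathTrace(samples=x, sample_rate_hz=sample_rate_hz)
    return trace, onsets_arr[keep], ends_arr[keep]


def schedule_stimulus(spec: StimulusSpec, breath) -> float:
    """Actual stimulus onset: first inhalation end at or after the later of
    the requested onset and the minimum prestimulus period.

    ``breath`` may be a :class:`BreathTrace` with events filled, or a sequence
    of inhalation-end times. Raises ``ValueError`` when no eligible
    inhalation end exists before the end of the trial.
    """
    ends = np.asarray(
        breath.inhalation_ends_s if isinstance(breath, BreathTrace) else breath,
        dtype=float,
    )
    earliest = max(spec.requested_onset_s, spec.min_prestimulus_s)
    eligible = ends[ends >= earliest]
    if eligible.size == 0:
        raise ValueError(
            f"no inhalation end at or after t={earliest:.3f} s; cannot schedule stimulus"
        )
    return float(eligible[0])


# ---------------------------------------------------------------------------
# rendering


def calcium_kernel(t_s: np.ndarray, rise_s: float = KERNEL_RISE_S,
                   decay_s: float = KERNEL_DECAY_S) -> np.ndarray:
    """Causal double-exponential calcium-transient kernel (unnormalized)."""
    k = np.where(t_s >= 0, np.exp(-np.maximum(t_s, 0) / decay_s)
                 - np.exp(-np.maximum(t_s, 0) / rise_s), 0.0)
    return k


def _baseline_field(shape: tuple[int, int], base_level: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Smooth, strictly positive baseline fluorescence field (coarse random
    surface upsampled with spline interpolation; ±10% spatial modulation)."""
    coarse = rng.normal(0.0, 1.0, size=(6, 6))
    h, w = shape
    surf = zoom(coarse, (h / 6, w / 6), order=3)[:h, :w]
    surf = surf / max(np.abs(surf).max(), 1e-12)
    return base_level * (1.0 + 0.1 * surf)


def _bleach_tau_map(acq: AcquisitionSpec) -> np.ndarray:
    h, w = acq.frame_shape
    tau = np.full((h, w), acq.bleach_tau_s)
    s = acq.quadrant_tau_scale
    tau[: h // 2, : w // 2] *= s[0]
    tau[: h // 2, w // 2:] *= s[1]
    tau[h // 2:, : w // 2] *= s[2]
    tau[h // 2:, w // 2:] *= s[3]
    return tau


def _blob_image(spec: MapSpec) -> tuple[np.ndarray, np.ndarray]:
    """Stacked per-glomerulus blob images (G, H, W) and their amplitudes-agnostic
    spatial profiles; profile peak is 1 at the center."""
    h, w = spec.frame_shape
    yy, xx = np.mgrid[0:h, 0:w]
    blobs = np.stack(
        [
            np.exp(
                -(((xx - g.center_x_px) ** 2) + ((yy - g.center_y_px) ** 2))
                / (2.0 * g.radius_px**2)
            )
            for g in spec.glomeruli
        ]
    ) if spec.glomeruli else np.zeros((0, h, w))
    return blobs, np.array([g.radius_px for g in spec.glomeruli])


def render_trial(
    maps: MapSpec,
    acq: AcquisitionSpec,
    breath: BreathTrace,
    true_onsets_s: np.ndarray,
    true_ends_s: np.ndarray,
    stim: StimulusSpec,
    onset_s: float,
    trial_seed: int | None = None,
) -> tuple[np.ndarray, GroundTruth]:
    """Render one trial movie (float32, T x H x W) with its ground truth.

    Forward model per pixel and frame::

        F = B(x, y) * (1 + sum_g amp_g * blob_g(x, y) * r(t)) * b(x, y, t) + noise

    where ``B`` is a smooth baseline field, ``r(t)`` is the sum of calcium
    kernels triggered at each inhalation onset during the odor pulse,
    normalized to unit mean over the 1.6-s response window starting at the
    first post-stimulus inhalation onset (the alignment anchor), and
    ``b = 1 - bleach_fraction * (1 - exp(-t / tau(x, y)))`` is the
    photobleaching factor. With that normalization the windowed ΔF/F0 at a
    blob center equals the glomerulus' effective amplitude exactly in the
    noiseless, bleach-free case.
    """
    rng = np.random.default_rng(acq.seed if trial_seed is None else trial_seed)
    n = acq.n_frames
    fs = acq.frame_rate_hz
    t = np.arange(n) / fs
    if breath.duration_s < n / fs - 1e-9:
        raise ValueError("breath trace shorter than the movie")

    onsets = np.asarray(true_onsets_s, dtype=float)
    after = onsets[onsets >= onset_s]
    if after.size == 0:
        raise ValueError("no inhalation onset after stimulus onset")
    anchor_s = float(after[0])
    anchor_frame = int(round(anchor_s * fs))
    resp_frames = seconds_to_frames(RESPONSE_WINDOW_S, fs)
    if anchor_frame + resp_frames > n:
        import warnings

        warnings.warn("response window truncated by end of trial", stacklevel=2)
        resp_frames = n - anchor_frame

    # breathing-coupled temporal response: one kernel per sniff during the pulse
    sniffs = onsets[(onsets >= onset_s) & (onsets < onset_s + stim.duration_s)]
    r = np.zeros(n)
    for ts in sniffs:
        r += calcium_kernel(t - ts)
    win = r[anchor_frame: anchor_frame + resp_frames]
    norm = float(win.mean()) if win.size else 0.0
    if norm <= 0:
        raise ValueError("degenerate response window; cannot calibrate amplitude")
    r /= norm

    scale = stim.amplitude_scale()
    amps = np.array([g.tuning.get(stim.odorant, 0.0) * scale for g in maps.glomeruli])
    blobs, _ = _blob_image(maps)
    # The anatomy (baseline fluorescence, bleach heterogeneity) is drawn in
    # dorsal coordinates and carried through the same mirror transform as the
    # glomeruli, so paired noiseless movies are exact mirror images.
    base = _baseline_field(acq.frame_shape, acq.base_level, rng)
    if maps.flip_applied:
        base = np.roll(np.flipud(base), maps.ap_offset_px, axis=1)

    spatial = (amps[:, None, None] * blobs).sum(axis=0) if blobs.shape[0] \
        else np.zeros(acq.frame_shape)
    spatial = spatial.astype(np.float32)
    movie = base.astype(np.float32)[None] * (
        np.float32(1.0) + r.astype(np.float32)[:, None, None] * spatial
    )
    if acq.bleach_fraction > 0:
        if len(set(acq.quadrant_tau_scale)) == 1:
            tau0 = acq.bleach_tau_s * acq.quadrant_tau_scale[0]
            factor = (1.0 - acq.bleach_fraction * (1.0 - np.exp(-t / tau0)))
            movie *= factor.astype(np.float32)[:, None, None]
        else:
            tau = _bleach_tau_map(acq)
            if maps.flip_applied:
                tau = np.roll(np.flipud(tau), maps.ap_offset_px, axis=1)
            movie *= (
                1.0 - acq.bleach_fraction
                * (1.0 - np.exp(-t[:, None, None] / tau[None]))
            ).astype(np.float32)
    if acq.noise_sd > 0:
        noise = rng.standard_normal(movie.shape, dtype=np.float32)
        noise *= np.float32(acq.noise_sd)
        movie += noise

    tau_blocks = _block_tau_table(acq)
    truth = GroundTruth(
        odorant=stim.odorant,
        concentration_pct=stim.nominal_concentration_pct,
        amplitudes=[float(a) for a in amps],
        centers_px=[(g.center_x_px, g.center_y_px) for g in maps.glomeruli],
        pair_ids=list(range(len(maps.glomeruli))),
        stimulus_onset_s=float(onset_s),
        anchor_time_s=anchor_s,
        anchor_frame=anchor_frame,
        inhalation_onsets_s=[float(x) for x in onsets],
        inhalation_ends_s=[float(x) for x in np.asarray(true_ends_s)],
        bleach_fraction=float(acq.bleach_fraction),
        bleach_tau_s_blocks=tau_blocks,
        ap_offset_px=maps.ap_offset_px,
        view=maps.view,
    )
    return movie.astype(np.float32), truth


def _block_tau_table(acq: AcquisitionSpec, block_size: int = 4) -> list[list[float]]:
    tau = _bleach_tau_map(acq)
    h, w = acq.frame_shape
    hb, wb = h // block_size, w // block_size
    if hb == 0 or wb == 0:
        return []
    return [
        [float(tau[i * block_size, j * block_size]) for j in range(wb)]
        for i in range(hb)
    ]


def render_activity_map(
    spec: MapSpec,
    odorant: str,
    noise_sd: float = 0.0,
    concentration_scale: float = 1.0,
    seed: int = 0,
) -> np.ndarray:
    """Render the ideal ΔF/F0 activity map for one odorant directly from a map
    spec (sum of amplitude-scaled blobs plus optional map-level Gaussian
    noise). Useful for testing the symmetry stage without full movies."""
    blobs, _ = _blob_image(spec)
    amps = np.array(
        [g.tuning.get(odorant, 0.0) * concentration_scale for g in spec.glomeruli]
    )
    out = (amps[:, None, None] * blobs).sum(axis=0) if blobs.shape[0] else np.zeros(
        spec.frame_shape
    )
    if noise_sd > 0:
        out = out + np.random.default_rng(seed).normal(0.0, noise_sd, size=out.shape)
    return out


# ---------------------------------------------------------------------------
# trial sets


def simulate_trial_set(
    maps: MapSpec,
    acq: AcquisitionSpec,
    breath_spec: BreathSpec,
    stim: StimulusSpec,
    n_trials: int = 4,
    seed: int = 0,
):
    """Simulate ``n_trials`` repeated presentations (default 4, matching the
    3-to-4-trial averaging convention) with independent breath jitter and
    sensor noise per trial.

    Returns a list of ``(movie, BreathTrace, actual_onset_s, GroundTruth)``.
    """
    ss = np.random.SeedSequence(seed)
    out = []
    for k, child in enumerate(ss.spawn(n_trials)):
        sub = child.generate_state(2)
        bspec = BreathSpec(
            rate_hz=breath_spec.rate_hz,
            duty_inhale=breath_spec.duty_inhale,
            jitter_sd_s=breath_spec.jitter_sd_s,
            amplitude=breath_spec.amplitude,
            noise_sd=breath_spec.noise_sd,
            seed=int(sub[0] % (2**31)),
        )
        trace, onsets, ends = generate_breath_trace(
            bspec, acq.duration_s, sample_rate_hz=acq.frame_rate_hz
        )
        onset = schedule_stimulus(stim, ends)
        movie, truth = render_trial(
            maps, acq, trace, onsets, ends, stim, onset,
            trial_seed=int(sub[1] % (2**31)),
        )
        out.append((movie, trace, onset, truth))
    return out
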