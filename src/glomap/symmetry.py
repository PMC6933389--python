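"""Mirror-symmetric map comparison.

The medial olfactory-bulb wall, imaged through a mirror-coated right-angle
prism, appears dorso-ventrally inverted and shifted along the
anterior-posterior axis by the prism placement. This module flips the medial
maps back, registers the anterior-posterior offset by 1-D normalized
cross-correlation, detects glomerular ROIs on the odorant-composite map,
matches homologous dorsal/medial ensembles by greedy nearest-neighbor
assignment, and quantifies chemotopic drift (the gradual shift of the
most-responsive glomerulus along a homologous odorant series) and
concentration-response consistency.

Image-axis convention throughout: rows = dorso-ventral axis (flipped by the
prism mirror), columns = anterior-posterior axis (registration axis).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from skimage.draw import disk
from skimage.feature import peak_local_max

from .activity import ActivityMap

__all__ = [
    "Roi",
    "GlomerulusSet",
    "Registration",
    "flip_medial",
    "register_ap_offset",
    "detect_glomeruli",
    "match_ensembles",
    "chemotopy_shift",
    "concentration_response",
    "robust_noise_sd",
]


@dataclass
class Roi:
    id: int
    centroid_px: tuple[float, float]  # (row, col)
    mask: np.ndarray  # H x W boolean, disjoint across the set
    amplitudes: dict[str, float]  # odorant -> mean ΔF/F0 over the mask

    @property
    def peak_amplitude(self) -> float:
        return max(self.amplitudes.values()) if self.amplitudes else 0.0


@dataclass
class GlomerulusSet:
    rois: list[Roi]
    view: str = "dorsal"  # 'dorsal' or 'medial_flipped'
    frame_shape: tuple[int, int] = (128, 128)


@dataclass(frozen=True)
class Registration:
    """Result of the anterior-posterior (column-axis) alignment search."""

    flip_axis: str  # always 'horizontal': rows are reversed
    ap_shift_px: int
    score: float  # normalized cross-correlation at the optimum, in [-1, 1]


def robust_noise_sd(image: np.ndarray) -> float:
    """Robust noise SD via the median absolute deviation (1.4826 * MAD)."""
    x = np.asarray(image, dtype=float).ravel()
    return float(1.4826 * np.median(np.abs(x - np.median(x))))


def flip_medial(amap: ActivityMap) -> ActivityMap:
    """Undo the prism's dorso-ventral inversion by reversing image rows.

    Applying it to an already-flipped map raises (involution guard); compose
    two explicit flips only via ``unflip=True``-style manual handling in
    tests. Records the flip in the metadata.
    """
    if amap.flipped:
        raise ValueError("map is already flipped; flipping twice undoes the correction")
    return replace(
        amap,
        values=amap.values[::-1].copy(),
        flipped=True,
        view="medial_flipped" if amap.view == "medial" else amap.view,
        floored_pixels=None if amap.floored_pixels is None
        else amap.floored_pixels[::-1].copy(),
    )


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a**2).sum() * (b**2).sum())
    if denom == 0:
        raise ValueError("zero-variance overlap; cannot normalize correlation")
    return float((a * b).sum() / denom)


def register_ap_offset(
    dorsal: ActivityMap | np.ndarray,
    medial_flipped: ActivityMap | np.ndarray,
    max_shift_px: int = 20,
) -> Registration:
    """Find the anterior-posterior offset between paired maps.

    Exhaustive search over integer column shifts in [-max_shift_px,
    +max_shift_px], maximizing the normalized cross-correlation of the
    overlapping region; ties break toward the smallest |shift|. The shift is
    the amount by which the flipped medial map must be moved along the
    columns to land on the dorsal map (i.e. minus the prism's
    anterior-posterior placement offset). NCC is invariant to adding a
    constant to either
    map. Raises ``ValueError`` when every overlap has zero variance.
    """
    d = np.asarray(dorsal.values if isinstance(dorsal, ActivityMap) else dorsal,
                   dtype=float)
    m = np.asarray(
        medial_flipped.values if isinstance(medial_flipped, ActivityMap)
        else medial_flipped, dtype=float)
    if d.shape != m.shape:
        raise ValueError(f"shape mismatch {d.shape} vs {m.shape}")
    w = d.shape[1]
    best: tuple[float, int] | None = None
    any_valid = False
    for s in sorted(range(-max_shift_px, max_shift_px + 1), key=lambda s: (abs(s), s)):
        # medial column c maps to dorsal column c + s
        if s >= 0:
            dv, mv = d[:, s:w], m[:, 0:w - s]
        else:
            dv, mv = d[:, 0:w + s], m[:, -s:w]
        if dv.size == 0:
            continue
        try:
            score = _ncc(dv, mv)
        except ValueError:
            continue
        any_valid = True
        if best is None or score > best[0]:
            best = (score, s)
    if not any_valid or best is None:
        raise ValueError("no shift produced a valid (nonzero-variance) overlap")
    return Registration(flip_axis="horizontal", ap_shift_px=best[1], score=best[0])


def detect_glomeruli(
    maps: list[ActivityMap] | list[np.ndarray],
    smooth_sigma: float = 1.0,
    threshold_sd: float = 3.0,
    roi_radius_px: int = 3,
    view: str = "dorsal",
    labels: list[str] | None = None,
) -> GlomerulusSet:
    """Detect glomerular ROIs on the pixelwise-max composite across odorants.

    The composite is Gaussian-smoothed (``smooth_sigma``); local maxima of the
    smoothed image exceeding ``median + threshold_sd * robust noise SD`` of
    the raw composite become ROI seeds, and each seed grows a disk of
    ``roi_radius_px``; where disks overlap the higher peak claims the pixels
    first (masks end up disjoint; peaks closer than ``roi_radius_px`` are
    merged into the stronger one). Per-ROI, per-odorant amplitudes are mask
    means over each input map (odorant names from the ActivityMaps, or
    ``labels`` for plain arrays). An empty set is a valid result.
    """
    if not maps:
        raise ValueError("need at least one map")
    arrays = [m.values if isinstance(m, ActivityMap) else np.asarray(m, float)
              for m in maps]
    if labels is None:
        labels = [m.odorant if isinstance(m, ActivityMap) else f"map{i}"
                  for i, m in enumerate(maps)]
    composite = np.max(np.stack(arrays), axis=0)
    smoothed = gaussian_filter(composite, smooth_sigma)
    thr = float(np.median(composite)) + threshold_sd * robust_noise_sd(composite)
    peaks = peak_local_max(
        smoothed, min_distance=roi_radius_px, threshold_abs=thr, exclude_border=False
    )
    if peaks.size == 0:
        return GlomerulusSet([], view=view, frame_shape=composite.shape)
    order = np.argsort(-smoothed[peaks[:, 0], peaks[:, 1]], kind="stable")
    claimed = np.zeros(composite.shape, dtype=bool)
    rois: list[Roi] = []
    for rank, pi in enumerate(order):
        r, c = int(peaks[pi, 0]), int(peaks[pi, 1])
        rr, cc = disk((r, c), roi_radius_px + 0.5, shape=composite.shape)
        mask = np.zeros(composite.shape, dtype=bool)
        mask[rr, cc] = True
        mask &= ~claimed
        if not mask.any():
            continue
        claimed |= mask
        amps = {lab: float(arr[mask].mean()) for lab, arr in zip(labels, arrays)}
        rois.append(Roi(id=rank, centroid_px=(float(r), float(c)), mask=mask,
                        amplitudes=amps))
    return GlomerulusSet(rois, view=view, frame_shape=composite.shape)


def match_ensembles(
    dorsal: GlomerulusSet,
    medial: GlomerulusSet,
    reg: Registration,
    gate_px: float = 5.0,
) -> pd.DataFrame:
    """Pair homologous glomeruli across the two views.

    Medial centroids (from the flipped map) are translated by the registered
    anterior-posterior shift, then pairs are formed greedily in ascending
    centroid distance, one-to-one, discarding candidates beyond ``gate_px``.
    Each pair carries the Pearson correlation of the per-odorant amplitude
    vectors. Empty inputs give an empty table.
    """
    cols = ["dorsal_id", "medial_id", "distance_px", "tuning_correlation"]
    if not dorsal.rois or not medial.rois:
        return pd.DataFrame(columns=cols)
    d_cent = np.array([r.centroid_px for r in dorsal.rois])
    m_cent = np.array([r.centroid_px for r in medial.rois], dtype=float)
    m_cent[:, 1] += reg.ap_shift_px
    dist = np.sqrt(((d_cent[:, None, :] - m_cent[None, :, :]) ** 2).sum(axis=2))
    pairs = sorted(
        ((dist[i, j], i, j) for i in range(len(dorsal.rois))
         for j in range(len(medial.rois)) if dist[i, j] <= gate_px)
    )
    used_d: set[int] = set()
    used_m: set[int] = set()
    rows = []
    for dval, i, j in pairs:
        if i in used_d or j in used_m:
            continue
        used_d.add(i)
        used_m.add(j)
        dr, mr = dorsal.rois[i], medial.rois[j]
        odors = sorted(set(dr.amplitudes) & set(mr.amplitudes))
        if len(odors) >= 2:
            a = np.array([dr.amplitudes[o] for o in odors])
            b = np.array([mr.amplitudes[o] for o in odors])
            with np.errstate(invalid="ignore"):
                corr = float(np.corrcoef(a, b)[0, 1])
        else:
            corr = float("nan")
        rows.append({"dorsal_id": dr.id, "medial_id": mr.id,
                     "distance_px": float(dval), "tuning_correlation": corr})
    return pd.DataFrame(rows, columns=cols)


def chemotopy_shift(
    gset: GlomerulusSet,
    ordered_panel: list[str],
    axis: tuple[float, float] = (1.0, 0.0),
    response_floor: float = 0.0,
) -> tuple[pd.DataFrame, bool]:
    """Position of the most-responsive glomerulus per odorant of an ordered
    homologous series, and whether it drifts monotonically.

    For each odorant the ROI with the largest amplitude (above
    ``response_floor``) contributes its centroid; odorants with no responsive
    ROI are marked absent and excluded from the monotonicity test. The flag
    is true iff the centroid projections onto ``axis`` (an (x, y) vector,
    default anterior-posterior/columns) are weakly monotone — in either
    direction, since the anatomical sign of the axis is view-dependent —
    across the panel order. Requires a panel of at least 3 odorants.
    """
    if len(ordered_panel) < 3:
        raise ValueError("ordered_panel must have at least 3 odorants")
    ax, ay = axis
    rows = []
    projections = []
    for od in ordered_panel:
        best: Roi | None = None
        for roi in gset.rois:
            a = roi.amplitudes.get(od, 0.0)
            if a >= response_floor and a > 0 and (
                best is None or a > best.amplitudes.get(od, 0.0)
            ):
                best = roi
        if best is None:
            rows.append({"odorant": od, "row": np.nan, "col": np.nan,
                         "projection": np.nan, "absent": True})
        else:
            r, c = best.centroid_px
            p = c * ax + r * ay
            projections.append(p)
            rows.append({"odorant": od, "row": r, "col": c, "projection": p,
                         "absent": False})
    table = pd.DataFrame(rows, columns=["odorant", "row", "col", "projection",
                                        "absent"])
    if len(projections) < 2:
        return table, False
    diffs = np.diff(projections)
    monotone = bool(np.all(diffs >= 0) or np.all(diffs <= 0))
    return table, monotone


def concentration_response(
    sets_by_concentration: dict[float, GlomerulusSet],
    response_floor: float,
) -> pd.DataFrame:
    """Responding-glomerulus counts across stimulus concentrations.

    For each concentration, counts the ROIs whose peak amplitude (max over
    odorants) reaches ``response_floor``. All sets must share a field of
    view. Amplitudes are reported per ROI so non-decreasing behavior with
    concentration can be inspected (it is reported, not enforced).
    """
    shapes = {s.frame_shape for s in sets_by_concentration.values()}
    if len(shapes) > 1:
        raise ValueError(f"mismatched fields of view: {sorted(shapes)}")
    rows = []
    for conc in sorted(sets_by_concentration):
        gset = sets_by_concentration[conc]
        amps = {r.id: r.peak_amplitude for r in gset.rois}
        rows.append(
            {
                "concentration_pct": conc,
                "n_responding": sum(a >= response_floor for a in amps.values()),
                "n_rois": len(gset.rois),
                "roi_amplitudes": amps,
            }
        )
    return pd.DataFrame(rows, columns=["concentration_pct", "n_responding",
                                       "n_rois", "roi_amplitudes"])
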