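# Methods

## Scope and model

`glomap` analyzes widefield calcium movies of the mouse olfactory bulb:
per-trial photobleaching correction, respiration-anchored trial averaging,
ΔF/F₀ activity mapping, and comparison of the dorsal glomerular map with the
medial map imaged through a mirror-coated right-angle prism (dorso-ventrally
inverted, shifted along the anterior–posterior axis by the prism placement).
Because no recordings of this preparation are publicly deposited, the package
ships a forward model (`glomap.synthetic`) that generates trials with
complete ground truth; every recovery claim below is a property of the
pipeline run on that generator, at the stated settings.

Axis convention: image rows are the dorso-ventral axis (reversed by the
prism mirror), image columns the anterior–posterior axis (registration axis).

## Synthetic forward model

A trial movie is

    F(x, y, t) = B(x, y) · (1 + Σ_g a_g · G_g(x, y) · r(t)) · b(x, y, t) + ε

- `B`: smooth positive baseline-fluorescence field (coarse 6×6 random
  surface, cubic-spline upsampled, ±10% modulation around `base_level`,
  default 1000 counts). For a paired medial trial the same field is carried
  through the mirror transform, so noiseless paired movies are exact mirror
  images.
- `G_g`: Gaussian glomerulus profile, σ = `radius_px` (default 5 px ≈ 70 µm
  at the 13.7 µm/px scale of a 1.75 mm / 128 px field — the blob includes
  widefield optical blur, which is why it is broader than an anatomical
  glomerulus radius).
- `r(t)`: sum of double-exponential calcium kernels (rise 0.05 s, decay
  0.6 s, GCaMP6f-like) triggered at every inhalation onset during the 2-s
  odor pulse, **normalized to unit mean over the 1.6-s response window**
  starting at the alignment anchor. The tuning amplitude `a_g` is therefore
  *defined* as the windowed ΔF/F₀ it produces at the blob center, making all
  downstream amplitude-recovery statements independent of the kernel shape.
- `b(x, y, t) = 1 − f·(1 − e^(−t/τ))`: multiplicative mono-exponential
  photobleaching (defaults f = 0.2, τ = 5 s in the recovery runs); an
  optional per-quadrant τ scaling makes it spatially heterogeneous (default
  uniform).
- `ε`: i.i.d. Gaussian sensor noise per pixel-frame (default SD 5 counts on
  a ~1000-count baseline). Shot noise is not modeled.

Acquisition defaults mirror the recording protocol: 128×128 px, 125 Hz, 13 s
(1,625 frames). Trials come in sets of 4 (3 after an exclusion is still
accepted) with independent breath jitter and noise.

### Breathing

The piezo-like trace is biphasic per cycle: a positive half-sine over the
inhalation (duty fraction 0.4 of the period) and a negative half-sine over
the exhalation scaled to equal area, so each cycle integrates to zero and the
zero-crossings coincide exactly with the ground-truth inhalation onsets/ends.
A raised-cosine-over-baseline waveform was rejected because its detrended
zero-crossing lags the true lobe onset by several samples, which would make
sub-sample onset recovery impossible by construction. Default rate 2 Hz
(anesthetized-mouse range; the true rate is preparation-dependent and
exposed in `BreathSpec`), cycle-period jitter SD 20 ms, trace noise SD 0.05
of the unit amplitude.

The stimulus command onset is the first inhalation *end* at or after
max(requested onset, 4 s minimum prestimulus), emulating delivery
synchronized to the end of inhalation; pulse duration 2 s.

### What the generator does not emulate

Optical PSF and vascular artifacts, motion, hemodynamic contamination,
spontaneous (non-odor) glomerular activity, shot noise, and rotational
misalignment of the prism view. Passing recovery tests therefore demonstrate
correctness of the algorithms under the stated statistical model, not
robustness to these real-data nuisances.

## Photobleaching correction

Frames are tiled into 4×4-px blocks (1,024 for a 128×128 frame). Each
block-mean trace is fitted with `a·e^(−t/τ) + c` using **only** the first 480
frames and the last 5 frames (exactly 485 samples per fit): the head
constrains the decay before odor arrival, the sparse tail anchors the
asymptote without letting late frames dominate. The nonlinear least-squares
fit (scipy `curve_fit`) is initialized from a log-linear fit of the
tail-subtracted head and bounded to τ ∈ [0.1 s, 10 × trial length]; fits
that fail, or whose amplitude is below twice the residual RMS, fall back to
amplitude 0 (correction becomes a no-op for that block).

Per pixel, the fitted curve is scaled by `k = p₀ / (a + c)` to match the
first-frame intensity and only the decaying component `k·a·e^(−t/τ)` is
subtracted. This **preserves the plateau** `k·c` as the corrected baseline:
subtracting the full scaled curve would zero the baseline and make the
subsequent ΔF/F₀ division ill-posed. Consequences:

- a pixel that is exactly a multiple of the fitted curve becomes constant;
- the correction is idempotent up to noise (re-correcting changes < 0.5%
  RMS);
- recovered response amplitudes carry a small positive bias
  ≈ f·e^(−t_anchor/τ) relative to a bleach-free recording (the transient
  rides on the bleached baseline but is divided by the preserved plateau);
  at the default f = 0.2, τ = 5 s and anchors near 6.5 s this is ~6–8%,
  within the 10% agreement bound against the bleach-free pipeline that the
  acceptance run measures.

Block-noise exclusion: the score is the time-averaged ratio of mean absolute
pixel differences across block boundaries to those within blocks (≈1 for
seamless images; both-gradients-zero defined as 1). Trials scoring above 2.0
are excluded — the threshold is a package default chosen so that clean
synthetic trials (score ≈ 1.01) pass with wide margin while i.i.d. per-block
offsets (score > 2 by construction) fail; the original criterion is not
quantified beyond "a few cases".

## Respiration detection and alignment

Boxcar low-pass (40 ms) → rolling-mean baseline subtraction (1 s) → optional
polarity flip (`auto` flips when >50% of detrended samples are positive,
i.e. inhalation is assumed the shorter phase) → upward zero-crossings as
onsets with a 150 ms refractory period, next downward crossing as the
inhalation end. Detection is invariant to positive rescaling of the trace.

On generator output the interior onsets are recovered to ±0.5 sample
noiseless and ≥95% within ±2 samples at default noise. Events within
~0.2 s of the trace edges (the onset at t = 0 and lobes truncated by the
recording end) are excluded from these statistics — no detector can recover
a crossing whose flanks are not recorded.

The alignment anchor is the first detected inhalation onset at or after the
stimulus command onset (inclusive boundary); frame index = round half away
from zero of anchor-time × frame rate.

## ΔF/F₀ maps

Trials are aligned by shifting frame axes so anchors coincide; the common
overlapping range of raw (bleach-corrected) intensities is averaged
pixel-wise *before* any division. Windows are half-open: response
`[anchor, anchor + round(1.6 s·rate))` (200 frames at 125 Hz, anchor frame
included), baseline `[anchor − round(1.4 s·rate), anchor − round(0.4 s·rate))`
(125 frames). The map is `(R − B)/B`; pixels whose baseline falls below 1%
of the movie's global median are zeroed and flagged. The map is exactly
invariant to positive rescaling of the movie.

## Mirror-map comparison

- **Flip**: row reversal; flipping an already-flipped map raises (involution
  guard).
- **Registration**: exhaustive integer column shifts in ±20 px maximizing
  the normalized cross-correlation of the overlap, ties toward the smaller
  |shift|. The reported shift moves the flipped medial map onto the dorsal
  map, i.e. equals *minus* the generator's prism offset. NCC makes the
  optimum invariant to additive offsets. A landmark-based override is
  possible by passing a user shift downstream; rotational misalignment is
  out of scope.
- **ROI detection** (invented here; the original analysis identified
  glomeruli visually): Gaussian-smooth (σ = 1 px) the pixelwise-max
  composite across odorants; seeds are local maxima above
  median + 3 × robust SD (1.4826·MAD) of the *raw* composite — the
  median-offset form keeps the threshold above the elevated noise floor a
  max-composite produces; seeds grow 3-px-radius disks, overlaps resolved by
  higher-peak priority (maxima closer than the disk radius merge into the
  stronger peak; masks are disjoint).
- **Matching**: medial centroids are shifted by the registered offset, then
  greedy nearest-neighbor one-to-one matching in ascending distance with a
  5-px gate; each pair carries the Pearson correlation of per-odorant
  amplitude vectors.
- **Chemotopy**: for an ordered odorant series (≥3 members), the centroid of
  the most-responsive ROI per odorant is projected on the A–P axis; the flag
  is true iff the projections are weakly monotone in either direction (the
  anatomical sign of the axis differs between views). Odorants with no
  responsive ROI are excluded from the test.
- **Concentration consistency**: per concentration, ROIs whose peak
  amplitude reaches the response floor are counted; the default floor is 2×
  the map's robust noise SD (no quantitative criterion exists in the
  original analysis). Monotonicity of amplitude with concentration is
  reported, not enforced.

## Problem sizes and determinism

Recovery statistics in the acceptance script and tests use: 20 bleached
trials (5 independent 4-trial sets) at full acquisition scale for the τ
statistic; one 4-trial set processed by the corrected and bleach-free
pipelines for amplitude agreement; 10 breath traces (~260 cycles) for onset
detection; 8-glomerulus map pairs with a 12-px prism offset for
registration, matching and chemotopy. These sizes keep a full run in the
minutes range on one CPU while giving stable medians. All randomness flows
from explicit seeds (`numpy` `default_rng` / `SeedSequence`); identical
seeds reproduce bit-identical movies, traces and manifests.

## Known limitations

- The correction's amplitude bias (above) is inherent to plateau-preserving
  subtraction; an unbiased variant would divide out the fitted bleach curve
  instead, which the original macro description does not do.
- Greedy matching is not globally optimal (Hungarian assignment would be),
  but is deterministic and adequate at the tested densities.
- The block-exclusion threshold, ROI radius, response floor and breathing
  rate are package defaults where the original analysis gives no number;
  all are exposed as parameters.
- Fixed-radius disk ROIs underestimate amplitudes of large glomeruli (edge
  dilution ~8% at the default blob size) — amplitude comparisons across
  views are unaffected because both views share the geometry.
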