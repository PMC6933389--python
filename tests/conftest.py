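"""Shared fixtures: small synthetic scenes and one full-scale recovery run.

The full-scale run (default acquisition: 128x128 px, 125 Hz, 1,625 frames,
bleach fraction 0.2 with tau 5 s, sensor noise on) is expensive, so it is
computed once per session and shared by the recovery tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from glomap.activity import Trial, TrialSet, average_aligned_trials, compute_activity_map
from glomap.bleach import correct_movie
from glomap.respiration import detect_breath_events, find_alignment_anchor
from glomap.synthetic import (
    AcquisitionSpec,
    BreathSpec,
    Glomerulus,
    MapSpec,
    StimulusSpec,
    generate_map_pair,
    simulate_trial_set,
)

PANEL = ["3CHO", "4CHO", "5CHO", "6CHO", "7CHO"]
RATE = 125.0


@pytest.fixture(scope="session")
def small_map() -> MapSpec:
    """One bright glomerulus in a 32x32 frame."""
    g = Glomerulus(16.0, 16.0, 6.0, {"5CHO": 0.05})
    return MapSpec((g,), frame_shape=(32, 32))


@pytest.fixture(scope="session")
def small_acq_quiet() -> AcquisitionSpec:
    return AcquisitionSpec(frame_shape=(32, 32), noise_sd=0.0, bleach_fraction=0.0)


def run_dff_pipeline(map_spec, acq, stim, n_trials=4, seed=42, correct=False):
    """Simulate a trial set, optionally bleach-correct, align, average, map.

    Returns (ActivityMap, GroundTruth of the last trial).
    """
    raws = simulate_trial_set(map_spec, acq, BreathSpec(), stim,
                              n_trials=n_trials, seed=seed)
    trials = []
    truth = None
    for k, (movie, trace, onset, truth) in enumerate(raws):
        m = np.asarray(movie, dtype=float)
        if correct:
            m, report = correct_movie(m, acq.frame_rate_hz)
            if report.excluded:
                continue
        trace = detect_breath_events(trace)
        anchor = find_alignment_anchor(trace, onset, acq.frame_rate_hz)
        trials.append(
            Trial(m, acq.frame_rate_hz, trace, stim.odorant,
                  stim.nominal_concentration_pct, onset, anchor.anchor_frame,
                  f"t{k}")
        )
    avg, anchor_frame = average_aligned_trials(TrialSet(trials))
    amap = compute_activity_map(avg, anchor_frame, acq.frame_rate_hz,
                                odorant=stim.odorant, n_trials=len(trials))
    return amap, truth


@pytest.fixture(scope="session")
def fullscale_recovery():
    """Default-scale recovery run shared by the acceptance tests.

    Renders 20 independent bleached noisy trials for the per-block tau
    statistic, plus one 4-trial set processed through the bleach-corrected
    and the bleach-free pipelines for amplitude comparison.
    """
    dorsal, _ = generate_map_pair(8, PANEL, seed=1)
    stim = StimulusSpec("5CHO")
    acq_bleach = AcquisitionSpec(bleach_fraction=0.2, bleach_tau_s=5.0, noise_sd=5.0)
    acq_clean = AcquisitionSpec(bleach_fraction=0.0, noise_sd=5.0)

    tau_errors = []
    for rep in range(5):
        raws = simulate_trial_set(dorsal, acq_bleach, BreathSpec(), stim,
                                  n_trials=4, seed=100 + rep)
        for movie, _, _, truth in raws:
            _, report = correct_movie(np.asarray(movie, float),
                                      acq_bleach.frame_rate_hz)
            taus = np.array([f.tau_s for f in report.fits if f.converged])
            tau_errors.append(np.median(np.abs(taus - 5.0) / 5.0))

    amap_corr, truth = run_dff_pipeline(dorsal, acq_bleach, stim, seed=42,
                                        correct=True)
    amap_free, _ = run_dff_pipeline(dorsal, acq_clean, stim, seed=42,
                                    correct=False)

    def center_amps(amap):
        return np.array(
            [amap.values[int(round(y)), int(round(x))]
             for (x, y) in truth.centers_px]
        )

    return {
        "tau_median_errors": np.array(tau_errors),
        "true_amps": np.array(truth.amplitudes),
        "amps_corrected": center_amps(amap_corr),
        "amps_bleach_free": center_amps(amap_free),
    }
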