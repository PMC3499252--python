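"""Canonical end-to-end study protocols on synthetic recordings.

These builders freeze the simulated study conditions — imaging geometry,
artifact and bleaching regimes, thrust regimes, behavioral regimes — so the
same protocol drives the test suite, the examples and the reproduction
script.  Each replicate runs the full pipeline (generate -> extract ->
fit -> correct -> call, or generate -> detect -> summarise) against the
generator's ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np

from .behavior import compute_esi
from .extract import RoiTrack, extract_traces
from .ratiometric import call_events, correct_and_dff, fit_reference
from .simulate import (
    StackSimConfig,
    ThrustSimConfig,
    TimelineSimConfig,
    generate_stack,
    generate_thrust_trace,
    generate_timeline,
    smooth_artifact_series,
)
from .thrust import detect_deflections

#: Imaging replicate conditions: 64x64 px, 300 frames at 30 frames/s (a 10 s
#: bout), one neuron, two planted transients with peaks drawn from the
#: 30-80% range seen at vulval contact, red bleaching of ~15% over the bout,
#: shared artifacts confined to a +/-20% band, pixel noise of 2% of the
#: green baseline.
STACK_N_FRAMES = 300
STACK_FRAME_RATE = 30.0
STACK_IMAGE_SIZE = (64, 64)
STACK_ARTIFACT_MAX_DEV = 0.2
STACK_NOISE_SD = 2.0
STACK_RED_BLEACH = (120.0, 30.0, 0.15)
TRANSIENT_ONSETS_S = (2.0, 6.0)
TRANSIENT_DURATION_S = 1.5
TRANSIENT_AMP_RANGE = (0.3, 0.8)


def standard_stack_config(seed: int) -> StackSimConfig:
    """One imaging replicate's generator configuration.

    The artifact series and transient amplitudes are drawn from ``seed``;
    the pixel-noise stream uses an offset seed so it is independent of the
    amplitude draw.
    """
    rng = np.random.default_rng(seed)
    artifact = smooth_artifact_series(
        STACK_N_FRAMES, rng, max_dev=STACK_ARTIFACT_MAX_DEV
    )
    amps = rng.uniform(*TRANSIENT_AMP_RANGE, size=len(TRANSIENT_ONSETS_S))
    schedule = [
        (onset, TRANSIENT_DURATION_S, float(a))
        for onset, a in zip(TRANSIENT_ONSETS_S, amps)
    ]
    return StackSimConfig(
        n_frames=STACK_N_FRAMES,
        frame_rate=STACK_FRAME_RATE,
        image_size=STACK_IMAGE_SIZE,
        cell_positions=[(20, 20)],
        baseline_green=100.0,
        baseline_red=150.0,
        background_level=10.0,
        transient_schedule=schedule,
        red_bleach=STACK_RED_BLEACH,
        artifact_series=artifact,
        noise_sd=STACK_NOISE_SD,
        seed=seed + 1000,
    )


def standard_roi_layout(n_frames: int) -> List[RoiTrack]:
    """The four-ROI layout of a dual-view recording: cell and background
    ROIs on each channel (cell rects over the neuron, backgrounds over an
    empty corner)."""
    return [
        RoiTrack.static("2", "cell", "green", (15, 15, 10, 10), n_frames),
        RoiTrack.static("4", "cell", "red", (15, 15, 10, 10), n_frames),
        RoiTrack.static("3", "background", "green", (50, 50, 8, 8), n_frames),
        RoiTrack.static("1", "background", "red", (50, 50, 8, 8), n_frames),
    ]


@dataclass
class RatiometricReplicate:
    """Outcome of one extract -> fit -> correct -> call replicate."""

    n_true_events: int
    n_called_events: int
    peak_errors_pct: List[float]  # |called peak - true per-frame peak|

    @property
    def recovered(self) -> bool:
        return self.n_called_events == self.n_true_events and all(
            e <= 5.0 for e in self.peak_errors_pct
        )


def run_ratiometric_replicate(seed: int) -> RatiometricReplicate:
    """Run the full imaging pipeline on one synthetic stack."""
    config = standard_stack_config(seed)
    stack, truth = generate_stack(config)
    traces = extract_traces(stack, standard_roi_layout(config.n_frames))
    fit = fit_reference(traces.bg_subtracted["4"], stack.times, mode="auto")
    corrected = correct_and_dff(
        traces.bg_subtracted["2"], traces.bg_subtracted["4"], fit, stack.times
    )
    calls = call_events(corrected)

    errors = []
    if calls.n_events == len(config.transient_schedule):
        for (onset, duration, _), event in zip(
            config.transient_schedule, calls.events
        ):
            lo = int(onset * config.frame_rate)
            hi = int((onset + duration) * config.frame_rate) + 1
            true_peak = truth.true_dff[0][lo:hi].max()
            errors.append(abs(event.peak_dff_pct - true_peak))
    return RatiometricReplicate(
        n_true_events=len(config.transient_schedule),
        n_called_events=calls.n_events,
        peak_errors_pct=errors,
    )


#: Thrust replicate conditions: 10 s bouts at 35 samples/s, 10% deflection
#: amplitude, 10 ms timing jitter, no dropped cycles.
THRUST_DURATION_S = 10.0
THRUST_AMPLITUDE_PCT = 10.0
THRUST_JITTER_SD_S = 0.010


def run_thrust_replicate(frequency: float, seed: int) -> Tuple[float, int, int]:
    """One thrust bout: returns (estimated frequency Hz, n detected, n true)."""
    config = ThrustSimConfig(
        frequency=frequency,
        duration=THRUST_DURATION_S,
        amplitude_pct=THRUST_AMPLITUDE_PCT,
        jitter_sd=THRUST_JITTER_SD_S,
        dropout_prob=0.0,
        seed=seed,
    )
    trace, truth_times = generate_thrust_trace(config)
    detected = detect_deflections(trace)
    return detected.mean_freq, detected.n_deflections, len(truth_times)


#: Behavioral regimes: a wild-type-like male prods mostly at the vulva; a
#: dopamine-deficient-like male prods ectopically most of the time.
BASELINE_REGIME = dict(p_ectopic=0.2)
ECTOPIC_REGIME = dict(p_ectopic=0.8)


def esi_regime_median(
    p_ectopic: float, n_males: int, base_seed: int
) -> float:
    """Median E_SI over ``n_males`` simulated timelines of one regime."""
    scores = []
    for i in range(n_males):
        timeline = generate_timeline(
            TimelineSimConfig(p_ectopic=p_ectopic, seed=base_seed + i)
        )
        scores.append(compute_esi(timeline).score)
    return float(np.median(scores))
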