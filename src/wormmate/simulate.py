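"""Synthetic recordings with known ground truth.

Everything downstream of the camera is testable against this module: it
generates two-channel image stacks with planted calcium transients,
channel-specific photobleaching and shared per-frame artifacts; mating
timelines with scanning/prodding/insertion structure; and oscillatory
spicule-thrust traces in the 7-11 Hz regime.

Generative pixel model (per frame time t):

* green cell pixel  = baseline_green * (1 + transient(t)) * exp(-g_rate*t)
                      * artifact(t) + background + noise
* red cell pixel    = (plateau + span * exp(-rate*t)) * artifact(t)
                      + background + noise
* background pixel  = background + noise

The per-frame artifact factor is shared by both channels — the property the
ratiometric correction exploits.  All randomness flows from one seeded
``numpy.random.Generator`` per call; identical seed and config give
bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .behavior import BehaviorTimeline, DEFAULT_OBSERVATION_CAP
from .core import GREEN, RED, DualChannelStack
from .thrust import ThrustTrace


# --------------------------------------------------------------------------
# image stacks
# --------------------------------------------------------------------------

@dataclass
class StackSimConfig:
    """Parameters of a simulated dual-channel recording.

    ``transient_schedule`` lists planted calcium events as
    ``(onset_s, duration_s, peak_amplitude)`` with the amplitude expressed as
    a fraction of the green baseline (0.5 -> a 50% ΔF/F0 peak).  The same
    schedule is applied to every cell.  ``red_bleach`` is the one-phase-decay
    bleaching of the red reference, ``(plateau_au, span_au, rate_per_s)``.
    ``artifact_series`` is an optional per-frame multiplicative factor shared
    by both channels; when None a smoothed random walk confined to
    [0.7, 1.3] is drawn, emulating focusing/movement/illumination
    fluctuations of up to roughly 20-30%.
    """

    n_frames: int
    frame_rate: float = 30.0
    image_size: Tuple[int, int] = (64, 64)
    cell_positions: Sequence[Tuple[int, int]] = ((32, 32),)
    cell_radius: int = 4
    baseline_green: float = 100.0
    baseline_red: float = 150.0
    background_level: float = 10.0
    transient_schedule: Sequence[Tuple[float, float, float]] = ()
    red_bleach: Tuple[float, float, float] = (120.0, 30.0, 0.15)
    green_bleach_rate: float = 0.0
    artifact_series: Optional[np.ndarray] = None
    noise_sd: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_frames < 2:
            raise ValueError("n_frames must be at least 2")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        h, w = self.image_size
        if h <= 0 or w <= 0:
            raise ValueError("image_size must be positive")
        if self.baseline_green < 0 or self.baseline_red < 0:
            raise ValueError("baselines must be non-negative")
        if self.background_level < 0:
            raise ValueError("background_level must be non-negative")
        for onset, dur, amp in self.transient_schedule:
            if dur <= 0:
                raise ValueError("transient duration must be positive")
            if amp < 0:
                raise ValueError("transient amplitude must be non-negative")
        plateau, span, rate = self.red_bleach
        if plateau < 0 or span < 0 or rate < 0:
            raise ValueError("red_bleach parameters must be non-negative")
        if self.green_bleach_rate < 0:
            raise ValueError("green_bleach_rate must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.artifact_series is not None:
            art = np.asarray(self.artifact_series, dtype=float)
            if len(art) != self.n_frames:
                raise ValueError("artifact_series length must equal n_frames")
            if np.any(art <= 0):
                raise ValueError("artifact factors must be positive")


@dataclass
class StackGroundTruth:
    """What the generator planted, for parameter-recovery tests."""

    true_dff: np.ndarray          # (n_cells, n_frames) percent series
    transient_times: list         # [(onset_s, duration_s), ...]
    artifact_series: np.ndarray   # per-frame shared factor
    bleach_params: tuple          # (plateau, span, rate) of the red channel
    cell_masks: list              # boolean (h, w) mask per cell


def smooth_artifact_series(
    n_frames: int,
    rng: np.random.Generator,
    max_dev: float = 0.3,
    flicker_sd: float = 0.04,
    excursion_sd: float = 0.005,
    reversion: float = 0.2,
) -> np.ndarray:
    """Mean-one artifact factor series confined to ``[1-max_dev, 1+max_dev]``.

    Emulates the artifacts that hit both channels identically: frame-scale
    illumination (arc-lamp) flicker, modeled as white multiplicative noise
    of ``flicker_sd``, plus brief focusing/movement excursions, modeled as
    a mean-reverting random walk (an Ornstein-Uhlenbeck-style process with
    per-step ``reversion`` and stationary SD ``excursion_sd``).  Mean
    reversion keeps the excursions transient — the experimenter actively
    refocuses and recenters — rather than letting the level drift
    monotonically, which would be indistinguishable from photobleaching
    and is outside what a red-referenced correction can identify.
    """
    flicker = rng.normal(0.0, flicker_sd, size=n_frames)
    step_sd = excursion_sd * math.sqrt(2 * reversion - reversion**2)
    x = np.empty(n_frames)
    x[0] = rng.normal(0.0, excursion_sd)
    steps = rng.normal(0.0, step_sd, size=n_frames)
    for i in range(1, n_frames):
        x[i] = x[i - 1] * (1.0 - reversion) + steps[i]
    return np.clip(1.0 + flicker + x, 1.0 - max_dev, 1.0 + max_dev)


def transient_waveform(
    t: np.ndarray, onset: float, duration: float
) -> np.ndarray:
    """Unit-peak calcium transient: linear rise, exponential fall.

    The waveform rises linearly over the first quarter of ``duration`` and
    decays exponentially (time constant = duration/4) over the remainder; it
    is zero outside ``[onset, onset + duration]``.
    """
    t = np.asarray(t, dtype=float)
    rel = t - onset
    rise = duration / 4.0
    tau = duration / 4.0
    out = np.zeros_like(rel)
    up = (rel >= 0) & (rel < rise)
    out[up] = rel[up] / rise
    down = (rel >= rise) & (rel <= duration)
    out[down] = np.exp(-(rel[down] - rise) / tau)
    return out


def _transient_series(
    t: np.ndarray, schedule: Sequence[Tuple[float, float, float]]
) -> np.ndarray:
    total = np.zeros_like(np.asarray(t, dtype=float))
    for onset, duration, amplitude in schedule:
        total += amplitude * transient_waveform(t, onset, duration)
    return total


def _disc_mask(shape, center, radius) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def generate_stack(
    config: StackSimConfig,
) -> Tuple[DualChannelStack, StackGroundTruth]:
    """Render a dual-channel stack and its ground truth.

    Cells are filled discs of ``cell_radius`` pixels; their shape is
    irrelevant to mean-pixel-intensity analysis.  Raises ``ValueError`` for
    out-of-image or overlapping cells.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    h, w = config.image_size
    n = config.n_frames
    t = np.arange(n) / config.frame_rate

    masks = []
    occupied = np.zeros((h, w), dtype=bool)
    for pos in config.cell_positions:
        r, c = pos
        if not (
            config.cell_radius <= r < h - config.cell_radius
            and config.cell_radius <= c < w - config.cell_radius
        ):
            raise ValueError(
                f"cell at {pos} does not fit inside a {h}x{w} image "
                f"with radius {config.cell_radius}"
            )
        mask = _disc_mask((h, w), pos, config.cell_radius)
        if np.any(mask & occupied):
            raise ValueError(f"cell at {pos} overlaps another cell")
        occupied |= mask
        masks.append(mask)

    if config.artifact_series is not None:
        artifact = np.asarray(config.artifact_series, dtype=float).copy()
    else:
        artifact = smooth_artifact_series(n, rng)

    transient = _transient_series(t, config.transient_schedule)
    green_cell = (
        config.baseline_green
        * (1.0 + transient)
        * np.exp(-config.green_bleach_rate * t)
        * artifact
    )
    plateau, span, rate = config.red_bleach
    red_cell = (plateau + span * np.exp(-rate * t)) * artifact

    data = np.full((n, h, w, 2), float(config.background_level))
    for mask in masks:
        data[:, mask, GREEN] += green_cell[:, None]
        data[:, mask, RED] += red_cell[:, None]
    if config.noise_sd > 0:
        data += rng.normal(0.0, config.noise_sd, size=data.shape)
        np.clip(data, 0.0, None, out=data)

    true_dff = np.tile(100.0 * transient, (len(masks), 1))
    truth = StackGroundTruth(
        true_dff=true_dff,
        transient_times=[(on, du) for on, du, _ in config.transient_schedule],
        artifact_series=artifact,
        bleach_params=config.red_bleach,
        cell_masks=masks,
    )
    return DualChannelStack(data, config.frame_rate), truth


# --------------------------------------------------------------------------
# mating timelines
# --------------------------------------------------------------------------

@dataclass
class TimelineSimConfig:
    """Parameters of a simulated mating timeline.

    Bout lengths are exponential with the given means; prodding bouts are
    ectopic (off-vulva, emitted with the non-productive ``scanning`` label)
    with probability ``p_ectopic``.  Each on-vulva prodding bout ends in a
    penetration with probability ``p_penetration_per_bout``; penetration
    terminates the observation.  Defaults emulate a wild-type-like male; a
    dopamine-deficient-like regime is obtained by raising ``p_ectopic``.
    """

    observation_cap: float = DEFAULT_OBSERVATION_CAP
    p_ectopic: float = 0.2
    mean_scan_bout: float = 10.0
    mean_prod_bout: float = 8.0
    p_penetration_per_bout: float = 0.25
    seed: int = 0

    def validate(self) -> None:
        for p in (self.p_ectopic, self.p_penetration_per_bout):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.mean_scan_bout <= 0 or self.mean_prod_bout <= 0:
            raise ValueError("bout means must be positive")
        if self.observation_cap <= 0:
            raise ValueError("observation_cap must be positive")


#: Nominal duration recorded for the terminal insertion interval (s); the
#: observation stops at penetration, so only its start matters downstream.
INSERTION_INTERVAL_S = 0.5


def generate_timeline(config: TimelineSimConfig) -> BehaviorTimeline:
    """Sample one male's mating timeline.

    The male is in contact from t = 0 and alternates scanning and prodding
    bouts; the first bout type is drawn uniformly.  The timeline is
    truncated at the observation cap or at the first penetration.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    cap = config.observation_cap
    intervals = []
    t = 0.0
    prodding = bool(rng.random() < 0.5)
    while t < cap:
        if prodding:
            dur = rng.exponential(config.mean_prod_bout)
            ectopic = bool(rng.random() < config.p_ectopic)
            label = "scanning" if ectopic else "vulva_prodding"
            end = min(t + dur, cap)
            intervals.append((t, end, label))
            penetrates = (
                not ectopic
                and t + dur <= cap
                and rng.random() < config.p_penetration_per_bout
            )
            if penetrates:
                intervals.append((end, end + INSERTION_INTERVAL_S, "insertion"))
                return BehaviorTimeline(intervals, observation_cap=cap)
            t = end
        else:
            dur = rng.exponential(config.mean_scan_bout)
            end = min(t + dur, cap)
            intervals.append((t, end, "scanning"))
            t = end
        prodding = not prodding
    return BehaviorTimeline(intervals, observation_cap=cap)


# --------------------------------------------------------------------------
# spicule-thrust traces
# --------------------------------------------------------------------------

@dataclass
class ThrustSimConfig:
    """Parameters of a simulated spicule-thrust variability trace.

    The trace emulates the per-frame standard deviation of pixel intensity
    over a spicule ROI while the male prods the vulva at ``frequency`` Hz.
    ``amplitude_pct`` is the deflection amplitude as a percent of the quiet
    baseline; ``jitter_sd`` perturbs each cycle's timing; each cycle is
    skipped with probability ``dropout_prob``.
    """

    frequency: float = 9.0
    duration: float = 8.0
    sample_rate: float = 35.0
    amplitude_pct: float = 10.0
    jitter_sd: float = 0.0
    dropout_prob: float = 0.0
    noise_pct: float = 1.0
    baseline: float = 100.0
    seed: int = 0

    def validate(self) -> None:
        if self.frequency <= 0:
            raise ValueError("frequency must be positive")
        if self.sample_rate <= 2.0 * self.frequency:
            raise ValueError(
                "sample_rate must exceed twice the thrust frequency "
                "(aliasing)"
            )
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.amplitude_pct < 0 or self.noise_pct < 0:
            raise ValueError("percent amplitudes must be non-negative")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be non-negative")
        if not 0.0 <= self.dropout_prob <= 1.0:
            raise ValueError("dropout_prob must lie in [0, 1]")
        if self.baseline <= 0:
            raise ValueError("baseline must be positive")


#: Trapezoidal deflection shape: full amplitude within ±TOP_HALF_WIDTH_S of
#: the cycle centre, linear fall to zero at ±BASE_HALF_WIDTH_S.  A thrust is
#: brief relative to the dwell between thrusts, and the 30 ms flat top
#: guarantees a full-amplitude sample at the ~35 samples/s recording rate.
TOP_HALF_WIDTH_S = 0.015
BASE_HALF_WIDTH_S = 0.020


def _trapezoid(offsets: np.ndarray) -> np.ndarray:
    a = np.abs(offsets)
    out = np.zeros_like(a)
    out[a <= TOP_HALF_WIDTH_S] = 1.0
    ramp = (a > TOP_HALF_WIDTH_S) & (a < BASE_HALF_WIDTH_S)
    out[ramp] = (BASE_HALF_WIDTH_S - a[ramp]) / (
        BASE_HALF_WIDTH_S - TOP_HALF_WIDTH_S
    )
    return out


def generate_thrust_trace(
    config: ThrustSimConfig,
) -> Tuple[ThrustTrace, np.ndarray]:
    """Sample a thrust-variability trace and its true deflection times.

    Returns the trace (times, sd_mpi) and the ground-truth deflection times
    (cycle centres of the non-dropped cycles) in seconds.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = int(round(config.duration * config.sample_rate))
    times = np.arange(n) / config.sample_rate

    n_cycles = int(math.floor(config.frequency * config.duration))
    centers = (np.arange(n_cycles) + 0.5) / config.frequency
    if config.jitter_sd > 0:
        centers = centers + rng.normal(0.0, config.jitter_sd, size=n_cycles)
    keep = rng.random(n_cycles) >= config.dropout_prob
    centers = np.sort(centers[keep])
    centers = centers[(centers >= 0) & (centers < config.duration)]
    if config.amplitude_pct == 0:
        centers = centers[:0]

    signal = np.zeros(n)
    for c in centers:
        lo = np.searchsorted(times, c - BASE_HALF_WIDTH_S)
        hi = np.searchsorted(times, c + BASE_HALF_WIDTH_S, side="right")
        signal[lo:hi] = np.maximum(signal[lo:hi], _trapezoid(times[lo:hi] - c))

    sd = config.baseline * (1.0 + (config.amplitude_pct / 100.0) * signal)
    if config.noise_pct > 0:
        sd = sd + rng.normal(
            0.0, config.baseline * config.noise_pct / 100.0, size=n
        )
        sd = np.clip(sd, 0.0, None)
    return ThrustTrace(times=times, sd_mpi=sd), centers
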