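"""Spicule-thrust rhythmicity from intensity-variability traces.

During an insertion attempt the male thrusts his spicules against the
vulval slit at 7-11 Hz.  Each thrust churns the pixels inside a rectangular
ROI drawn over the spicule, so the per-frame standard deviation of pixel
intensity (the SD trace) oscillates with the thrust cycle.  A deflection is
scored whenever an oscillation peak exceeds the baseline by more than 5%,
and rhythmicity is summarised by the mean thrust frequency and the spread
of inter-thrust intervals — arrhythmic mutants show a larger interval SD.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .core import DualChannelStack


@dataclass
class ThrustTrace:
    """Per-frame pixel-intensity SD over the spicule ROI for one bout.

    ``normalized_pct`` expresses the trace as percent deviation from a
    baseline level; by default the baseline is the median of the bout,
    which resists contamination by the deflection peaks themselves.
    """

    times: np.ndarray
    sd_mpi: np.ndarray
    baseline: Optional[float] = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.sd_mpi = np.asarray(self.sd_mpi, dtype=float)
        if len(self.times) != len(self.sd_mpi):
            raise ValueError("times and sd_mpi lengths differ")
        if self.baseline is None and len(self.sd_mpi):
            self.baseline = float(np.median(self.sd_mpi))

    @property
    def normalized_pct(self) -> np.ndarray:
        if not len(self.sd_mpi):
            return self.sd_mpi.copy()
        if self.baseline is None or self.baseline <= 0:
            raise ValueError("baseline must be positive to normalize")
        return 100.0 * (self.sd_mpi - self.baseline) / self.baseline

    @property
    def sample_rate(self) -> float:
        if len(self.times) < 2:
            raise ValueError("need at least two samples for a sample rate")
        return 1.0 / float(np.median(np.diff(self.times)))


@dataclass
class DeflectionSet:
    """Detected thrusts of one bout and their interval statistics."""

    deflection_times: np.ndarray
    intervals: np.ndarray
    mean_freq: float
    interval_sd: float

    @classmethod
    def from_times(cls, times: np.ndarray) -> "DeflectionSet":
        times = np.asarray(times, dtype=float)
        if len(times) >= 2 and not np.all(np.diff(times) > 0):
            raise ValueError("deflection times must be strictly increasing")
        intervals = np.diff(times)
        if len(times) >= 2:
            mean_freq = (len(times) - 1) / (times[-1] - times[0])
        else:
            mean_freq = float("nan")
        interval_sd = float(np.std(intervals)) if len(intervals) else float("nan")
        return cls(
            deflection_times=times,
            intervals=intervals,
            mean_freq=float(mean_freq),
            interval_sd=interval_sd,
        )

    @property
    def n_deflections(self) -> int:
        return len(self.deflection_times)


def sd_trace(
    stack, roi, baseline: str = "median", frame_rate: float = 35.0
) -> ThrustTrace:
    """Per-frame population SD of pixel intensity inside a rectangular ROI.

    ``stack`` may be a :class:`~wormmate.core.DualChannelStack` (the ROI's
    channel is used and ``frame_rate`` is taken from the stack) or a plain
    ``(n_frames, height, width)`` grey-scale array sampled at
    ``frame_rate``.  ``baseline`` is ``"median"`` (default) or ``"mean"``
    of the bout's SD trace.
    """
    if isinstance(stack, DualChannelStack):
        frames = stack.channel(roi.channel)
        frame_rate = stack.frame_rate
    else:
        frames = np.asarray(stack, dtype=float)
        if frames.ndim != 3:
            raise ValueError("grey-scale stack must be (n_frames, h, w)")

    rects = roi.rects
    if len(rects) != len(frames):
        raise ValueError(
            f"ROI has {len(rects)} rects for {len(frames)} frames"
        )
    sds = np.empty(len(frames))
    for f, (r0, c0, hh, ww) in enumerate(rects):
        if hh * ww < 2:
            raise ValueError("spicule ROI area must be at least 2 pixels")
        patch = frames[f, r0 : r0 + hh, c0 : c0 + ww]
        if patch.shape != (hh, ww):
            raise ValueError(f"ROI rect out of bounds at frame {f}")
        sds[f] = patch.std()  # population SD
    times = np.arange(len(frames)) / frame_rate
    trace = ThrustTrace(times=times, sd_mpi=sds)
    if baseline == "mean":
        trace.baseline = float(np.mean(sds))
    elif baseline != "median":
        raise ValueError("baseline must be 'median' or 'mean'")
    return trace


def detect_deflections(
    trace: ThrustTrace,
    amplitude_threshold_pct: float = 5.0,
    refractory_s: float = 0.030,
) -> DeflectionSet:
    """Score one deflection per oscillation exceeding the amplitude criterion.

    Local maxima of the baseline-normalized trace above
    ``amplitude_threshold_pct`` are kept; maxima closer together than the
    refractory window are collapsed onto the larger one, suppressing
    double counts within a single thrust.
    """
    if amplitude_threshold_pct <= 0:
        raise ValueError("amplitude threshold must be positive")
    if not len(trace.times) or trace.times[-1] - trace.times[0] < 1.0:
        raise ValueError(
            "trace spans less than 1 s; not a scoreable prodding bout"
        )
    norm = trace.normalized_pct
    distance = max(1, int(round(refractory_s * trace.sample_rate)))
    peaks, _ = find_peaks(norm, height=amplitude_threshold_pct, distance=distance)
    return DeflectionSet.from_times(trace.times[peaks])


@dataclass
class RhythmicitySummary:
    """Per-bout frequency statistics and the pooled interval distribution."""

    per_animal: pd.DataFrame
    pooled_intervals: np.ndarray


def rhythmicity_summary(sets: Sequence[DeflectionSet]) -> RhythmicitySummary:
    """Summarise a group of bouts for cross-genotype comparison.

    One row per bout: deflection count, mean thrust frequency (Hz) and the
    SD of inter-thrust intervals (s); a larger interval SD indicates less
    rhythmic thrusting.  All intervals are pooled for distribution-level
    comparisons.
    """
    rows = []
    pooled = []
    for i, ds in enumerate(sets):
        rows.append(
            {
                "animal": i,
                "n_deflections": ds.n_deflections,
                "mean_freq_hz": ds.mean_freq,
                "interval_sd_s": ds.interval_sd,
            }
        )
        pooled.append(ds.intervals)
    per_animal = pd.DataFrame(
        rows, columns=["animal", "n_deflections", "mean_freq_hz", "interval_sd_s"]
    )
    pooled_arr = (
        np.concatenate(pooled) if pooled else np.empty(0, dtype=float)
    )
    return RhythmicitySummary(per_animal=per_animal, pooled_intervals=pooled_arr)
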