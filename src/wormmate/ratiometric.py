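"""Red-channel-referenced correction, %ΔF/F0, and calcium-event calling.

The red reference fluorophore is calcium-insensitive, so once background is
subtracted any change in its MPI reflects a shared experimental artifact
(focusing, gross movement, illumination flicker) or red-specific
photobleaching.  A reference line R(t) — the mean of the red trace, or a
one-phase decay ``plateau + span * exp(-rate * t)`` when the red channel
bleaches — is fitted; the per-frame correction value is

    c(t) = red_bg_subtracted(t) / R(t)

and the corrected green trace is ``G_corr(t) = green_bg_subtracted(t) /
c(t)`` (equivalently multiplied by the inverse correction value).  Percent
fluorescence change is then computed against the first frame:

    %ΔF/F0(t) = 100 * (G_corr(t) - G_corr(0)) / G_corr(0)

Focusing/motion artifacts can move %ΔF/F0 by up to about 20% even in
hyperpolarized-neuron controls, so calcium events are only called where the
trace exceeds a configurable artifact band (default 20%); genuine vulva-
contact transients reach 30-80%.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from scipy.optimize import curve_fit

DEFAULT_ARTIFACT_BAND_PCT = 20.0


@dataclass
class ReferenceFit:
    """Reference line fitted to the background-subtracted red trace.

    In ``mean`` mode the line is flat at the trace mean (span = 0,
    rate = 0); in ``one_phase_decay`` mode it is
    ``plateau + span * exp(-rate * t)`` from a bounded least-squares fit.
    """

    mode: str
    plateau: float
    span: float
    rate: float
    fitted: np.ndarray
    residual_sse: float


@dataclass
class CorrectedTrace:
    """Artifact-corrected green trace and its %ΔF/F0 representation."""

    times: np.ndarray
    correction: np.ndarray
    green_corrected: np.ndarray
    f0: float
    dff_pct: np.ndarray


@dataclass
class CalciumEvent:
    onset_frame: int
    offset_frame: int  # inclusive
    peak_frame: int
    peak_dff_pct: float


@dataclass
class EventCallSet:
    artifact_band_pct: float
    events: List[CalciumEvent]

    @property
    def n_events(self) -> int:
        return len(self.events)


def _one_phase_decay(t, plateau, span, rate):
    return plateau + span * np.exp(-rate * t)


def fit_reference(
    red: np.ndarray,
    times: np.ndarray,
    mode: str = "auto",
    sse_improvement: float = 0.05,
) -> ReferenceFit:
    """Fit the red-reference line.

    ``mode``:

    * ``"mean"`` — flat line at the trace mean.
    * ``"one_phase_decay"`` — bounded least squares (plateau, span,
      rate >= 0), initialised at (min, max - min, 1/duration).  An
      all-constant trace degenerates to the mean-equivalent fit (span 0).
    * ``"auto"`` — fit the decay and fall back to the mean line when the
      fit fails, the fitted rate is 0, or the decay does not reduce the
      SSE by at least ``sse_improvement`` (fractional) over the mean line.

    Raises ``ValueError`` if the fitted reference is not positive at every
    frame (the correction value would be undefined).
    """
    red = np.asarray(red, dtype=float)
    times = np.asarray(times, dtype=float)
    if len(red) != len(times):
        raise ValueError("red and times lengths differ")
    if len(red) < 3:
        raise ValueError("at least 3 frames are required to fit a reference")
    if not np.all(np.isfinite(red)):
        raise ValueError("red trace contains non-finite values")
    if mode not in ("auto", "mean", "one_phase_decay"):
        raise ValueError(f"unknown mode {mode!r}")

    mean_val = float(red.mean())
    mean_fit = ReferenceFit(
        mode="mean",
        plateau=mean_val,
        span=0.0,
        rate=0.0,
        fitted=np.full_like(red, mean_val),
        residual_sse=float(((red - mean_val) ** 2).sum()),
    )

    def check(fit: ReferenceFit) -> ReferenceFit:
        if np.any(fit.fitted <= 0):
            bad = int(np.argmax(fit.fitted <= 0))
            raise ValueError(
                f"fitted reference is non-positive at frame {bad}; "
                "correction undefined"
            )
        return fit

    if mode == "mean":
        return check(mean_fit)

    decay_fit: Optional[ReferenceFit] = None
    if np.ptp(red) == 0:
        # constant series: decay degenerates to the mean line
        decay_fit = ReferenceFit(
            mode="one_phase_decay",
            plateau=mean_val,
            span=0.0,
            rate=0.0,
            fitted=np.full_like(red, mean_val),
            residual_sse=0.0,
        )
    else:
        duration = times[-1] - times[0]
        p0 = (
            max(float(red.min()), 1e-12),
            max(float(np.ptp(red)), 1e-12),
            1.0 / duration if duration > 0 else 1.0,
        )
        try:
            popt, _ = curve_fit(
                _one_phase_decay,
                times,
                red,
                p0=p0,
                bounds=([0.0, 0.0, 0.0], [np.inf, np.inf, np.inf]),
                maxfev=10000,
            )
            fitted = _one_phase_decay(times, *popt)
            decay_fit = ReferenceFit(
                mode="one_phase_decay",
                plateau=float(popt[0]),
                span=float(popt[1]),
                rate=float(popt[2]),
                fitted=fitted,
                residual_sse=float(((red - fitted) ** 2).sum()),
            )
        except RuntimeError:
            decay_fit = None

    if mode == "one_phase_decay":
        if decay_fit is None:
            raise ValueError("one-phase decay fit failed to converge")
        return check(decay_fit)

    # auto: prefer decay only when it clearly beats the mean line
    if (
        decay_fit is not None
        and decay_fit.rate > 0
        and decay_fit.residual_sse
        <= (1.0 - sse_improvement) * mean_fit.residual_sse
    ):
        return check(decay_fit)
    return check(mean_fit)


def correct_and_dff(
    green: np.ndarray,
    red: np.ndarray,
    fit: ReferenceFit,
    times: Optional[np.ndarray] = None,
) -> CorrectedTrace:
    """Apply the red-referenced correction and compute %ΔF/F0.

    F0 is the corrected green value of the first frame.  Raises
    ``ValueError`` naming the frame when a correction value is non-positive
    or when F0 is 0.
    """
    green = np.asarray(green, dtype=float)
    red = np.asarray(red, dtype=float)
    if green.shape != red.shape or len(green) != len(fit.fitted):
        raise ValueError("green, red and fitted reference lengths differ")
    correction = red / fit.fitted
    bad = np.where(correction <= 0)[0]
    if len(bad):
        raise ValueError(
            f"correction value non-positive at frame {int(bad[0])}"
        )
    green_corr = green / correction
    f0 = float(green_corr[0])
    if f0 == 0:
        raise ValueError("F0 (first-frame corrected green) is zero")
    dff = 100.0 * (green_corr - f0) / f0
    if times is None:
        times = np.arange(len(green), dtype=float)
    return CorrectedTrace(
        times=np.asarray(times, dtype=float),
        correction=correction,
        green_corrected=green_corr,
        f0=f0,
        dff_pct=dff,
    )


def call_events(
    trace,
    band_pct: float = DEFAULT_ARTIFACT_BAND_PCT,
    min_gap_frames: int = 3,
    min_duration_frames: int = 2,
) -> EventCallSet:
    """Call calcium events as excursions of %ΔF/F0 above the artifact band.

    Contiguous runs with ``dff_pct > band_pct`` are events; runs separated
    by fewer than ``min_gap_frames`` sub-threshold frames are merged, and
    events shorter than ``min_duration_frames`` are dropped.  ``trace`` may
    be a :class:`CorrectedTrace` or a bare %ΔF/F0 array.
    """
    if band_pct <= 0:
        raise ValueError("band_pct must be positive")
    dff = np.asarray(getattr(trace, "dff_pct", trace), dtype=float)
    if not len(dff):
        return EventCallSet(artifact_band_pct=band_pct, events=[])

    above = dff > band_pct
    runs: List[List[int]] = []
    start = None
    for i, flag in enumerate(above):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            runs.append([start, i - 1])
            start = None
    if start is not None:
        runs.append([start, len(dff) - 1])

    merged: List[List[int]] = []
    for run in runs:
        if merged and run[0] - merged[-1][1] - 1 < min_gap_frames:
            merged[-1][1] = run[1]
        else:
            merged.append(run)

    events = []
    for on, off in merged:
        if off - on + 1 < min_duration_frames:
            continue
        seg = dff[on : off + 1]
        peak_rel = int(np.argmax(seg))
        events.append(
            CalciumEvent(
                onset_frame=on,
                offset_frame=off,
                peak_frame=on + peak_rel,
                peak_dff_pct=float(seg[peak_rel]),
            )
        )
    return EventCallSet(artifact_band_pct=band_pct, events=events)
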