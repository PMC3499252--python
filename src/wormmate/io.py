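"""Readers and writers for the pipeline's on-disk formats.

Stacks travel as multi-page TIFF with frame-major page order (page
``2*f`` = green, page ``2*f + 1`` = red for frame ``f``); the frame rate is
stored as JSON in the TIFF description of the first page.  Tabular data
(ROIs, traces, timelines, deflections) are CSV with a header row; fitted
parameters, ground truth and event calls are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import List, Sequence

import numpy as np
import pandas as pd
import tifffile

from .behavior import BehaviorTimeline
from .core import DualChannelStack
from .extract import FluorescenceTraceSet, RoiTrack
from .ratiometric import CorrectedTrace, EventCallSet, ReferenceFit
from .thrust import DeflectionSet, ThrustTrace


# ---------------------------------------------------------------- stacks

def write_stack_tiff(path, stack: DualChannelStack) -> None:
    """Write a dual-channel stack as a frame-major multi-page TIFF."""
    data = stack.data.transpose(0, 3, 1, 2)  # (F, 2, H, W)
    pages = data.reshape(-1, *data.shape[2:]).astype(np.float32)
    tifffile.imwrite(
        path,
        pages,
        description=json.dumps(
            {"frame_rate": stack.frame_rate, "channels": ["green", "red"]}
        ),
    )


def read_stack_tiff(path, frame_rate: float | None = None) -> DualChannelStack:
    """Read a stack written by :func:`write_stack_tiff`.

    ``frame_rate`` overrides the value stored in the TIFF description
    (needed for files produced elsewhere without one).
    """
    with tifffile.TiffFile(path) as tif:
        pages = tif.asarray()
        if frame_rate is None:
            desc = tif.pages[0].description or ""
            try:
                frame_rate = float(json.loads(desc)["frame_rate"])
            except (json.JSONDecodeError, KeyError, TypeError):
                raise ValueError(
                    "TIFF carries no frame_rate metadata; pass frame_rate="
                )
    if pages.ndim != 3 or pages.shape[0] % 2:
        raise ValueError("expected an even number of single-channel pages")
    f = pages.shape[0] // 2
    data = pages.reshape(f, 2, *pages.shape[1:]).transpose(0, 2, 3, 1)
    return DualChannelStack(np.asarray(data, dtype=float), frame_rate)


# ----------------------------------------------------------------- ROIs

def write_roi_csv(path, tracks: Sequence[RoiTrack]) -> None:
    """ROI CSV: roi_id, role, channel, frame, row0, col0, height, width.

    Coordinates are 0-based, half-open, row-major.
    """
    rows = []
    for t in tracks:
        for f, (r0, c0, h, w) in enumerate(t.rects):
            rows.append(
                {
                    "roi_id": t.roi_id,
                    "role": t.role,
                    "channel": t.channel,
                    "frame": f,
                    "row0": r0,
                    "col0": c0,
                    "height": h,
                    "width": w,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_roi_csv(path) -> List[RoiTrack]:
    df = pd.read_csv(path)
    tracks = []
    for (roi_id, role, channel), grp in df.groupby(
        ["roi_id", "role", "channel"], sort=False
    ):
        grp = grp.sort_values("frame")
        expected = np.arange(len(grp))
        if not np.array_equal(grp["frame"].to_numpy(), expected):
            raise ValueError(f"ROI {roi_id!r} is missing frames")
        rects = grp[["row0", "col0", "height", "width"]].to_numpy()
        tracks.append(RoiTrack(str(roi_id), role, channel, rects))
    return tracks


# ---------------------------------------------------------------- traces

def write_trace_csv(path, traces: FluorescenceTraceSet) -> None:
    """Long-format trace CSV: frame, time_s, roi_id, mpi."""
    rows = []
    for roi_id, series in traces.raw_mpi.items():
        for f, (t, v) in enumerate(zip(traces.times, series)):
            rows.append({"frame": f, "time_s": t, "roi_id": roi_id, "mpi": v})
    pd.DataFrame(rows).to_csv(path, index=False)


def write_corrected_csv(
    path, trace: CorrectedTrace, green: np.ndarray, red: np.ndarray
) -> None:
    pd.DataFrame(
        {
            "frame": np.arange(len(trace.dff_pct)),
            "time_s": trace.times,
            "green_sub": np.asarray(green, dtype=float),
            "red_sub": np.asarray(red, dtype=float),
            "correction": trace.correction,
            "green_corr": trace.green_corrected,
            "dff_pct": trace.dff_pct,
        }
    ).to_csv(path, index=False)


def write_reference_fit_json(path, fit: ReferenceFit) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "mode": fit.mode,
                "plateau": fit.plateau,
                "span": fit.span,
                "rate": fit.rate,
                "residual_sse": fit.residual_sse,
            },
            indent=2,
        )
    )


def write_events_json(path, calls: EventCallSet) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "artifact_band_pct": calls.artifact_band_pct,
                "events": [
                    {
                        "onset_frame": e.onset_frame,
                        "offset_frame": e.offset_frame,
                        "peak_frame": e.peak_frame,
                        "peak_dff_pct": e.peak_dff_pct,
                    }
                    for e in calls.events
                ],
            },
            indent=2,
        )
    )


# -------------------------------------------------------------- timelines

def write_timeline_csv(path, timeline: BehaviorTimeline) -> None:
    """Timeline CSV: start_s, end_s, label."""
    pd.DataFrame(
        [
            {"start_s": s, "end_s": e, "label": lab}
            for s, e, lab in timeline.intervals
        ]
    ).to_csv(path, index=False)


def read_timeline_csv(path, observation_cap: float = 120.0) -> BehaviorTimeline:
    df = pd.read_csv(path)
    intervals = [
        (float(r.start_s), float(r.end_s), str(r.label))
        for r in df.itertuples()
    ]
    return BehaviorTimeline(intervals, observation_cap=observation_cap)


# ----------------------------------------------------------- thrust traces

def write_thrust_trace_csv(path, trace: ThrustTrace) -> None:
    """Thrust trace CSV: frame, time_s, sd_mpi, normalized_pct."""
    pd.DataFrame(
        {
            "frame": np.arange(len(trace.times)),
            "time_s": trace.times,
            "sd_mpi": trace.sd_mpi,
            "normalized_pct": trace.normalized_pct,
        }
    ).to_csv(path, index=False)


def read_thrust_trace_csv(path) -> ThrustTrace:
    df = pd.read_csv(path)
    return ThrustTrace(
        times=df["time_s"].to_numpy(), sd_mpi=df["sd_mpi"].to_numpy()
    )


def write_deflections_csv(path, deflections: DeflectionSet) -> None:
    pd.DataFrame({"time_s": deflections.deflection_times}).to_csv(
        path, index=False
    )


# ------------------------------------------------------------ ground truth

def write_ground_truth_json(path, truth) -> None:
    """Serialise a :class:`~wormmate.simulate.StackGroundTruth` (sans masks)."""
    Path(path).write_text(
        json.dumps(
            {
                "true_dff": np.asarray(truth.true_dff).tolist(),
                "transient_times": list(map(list, truth.transient_times)),
                "artifact_series": np.asarray(truth.artifact_series).tolist(),
                "bleach_params": list(truth.bleach_params),
            },
            indent=2,
        )
    )
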