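"""ROI fluorescence extraction: mean pixel intensity and background subtraction.

The raw quantity everywhere downstream is the mean pixel intensity (MPI):
the arithmetic mean of pixel values inside a region of interest for one
frame.  ROIs are axis-aligned rectangles of equal area across frames whose
positions may be adjusted per frame (the recordings follow a moving animal);
each cell ROI has a same-channel background ROI whose MPI is subtracted
frame by frame.

Coordinates are 0-based, half-open, row-major: a rect ``(row0, col0,
height, width)`` covers rows ``row0:row0+height`` and columns
``col0:col0+width``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence

import numpy as np

from .core import CHANNEL_INDEX, DualChannelStack

ROLES = ("cell", "background")


@dataclass
class RoiTrack:
    """Per-frame rectangles for one ROI on one channel.

    ``rects`` has one ``(row0, col0, height, width)`` row per frame; all
    rects must have the same, positive area.
    """

    roi_id: str
    role: str
    channel: str
    rects: np.ndarray

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"role must be one of {ROLES}, got {self.role!r}")
        if self.channel not in CHANNEL_INDEX:
            raise ValueError(f"channel must be 'green' or 'red', got {self.channel!r}")
        self.rects = np.asarray(self.rects, dtype=int)
        if self.rects.ndim != 2 or self.rects.shape[1] != 4:
            raise ValueError("rects must have shape (n_frames, 4)")
        areas = self.rects[:, 2] * self.rects[:, 3]
        if np.any(areas <= 0):
            raise ValueError("all rects must have positive area")
        if len(set(areas.tolist())) > 1:
            raise ValueError("ROI area must be equal across frames")

    @property
    def n_frames(self) -> int:
        return len(self.rects)

    @property
    def area(self) -> int:
        return int(self.rects[0, 2] * self.rects[0, 3])

    @classmethod
    def static(cls, roi_id, role, channel, rect, n_frames) -> "RoiTrack":
        """A track that keeps one rect fixed for all frames."""
        return cls(roi_id, role, channel, np.tile(np.asarray(rect), (n_frames, 1)))


@dataclass
class FluorescenceTraceSet:
    """Raw and background-subtracted MPI series for a set of ROIs."""

    times: np.ndarray
    raw_mpi: Dict[str, np.ndarray]
    bg_subtracted: Dict[str, np.ndarray]
    pairing: Dict[str, str]


def extract_mpi(stack: DualChannelStack, roi: RoiTrack) -> np.ndarray:
    """MPI series of one ROI: mean pixel value inside each frame's rect."""
    frames = stack.channel(roi.channel)
    n, h, w = frames.shape
    if roi.n_frames != n:
        raise ValueError(
            f"ROI {roi.roi_id!r} defines {roi.n_frames} rects for a "
            f"{n}-frame stack"
        )
    out = np.empty(n)
    for f, (r0, c0, hh, ww) in enumerate(roi.rects):
        if r0 < 0 or c0 < 0 or r0 + hh > h or c0 + ww > w:
            raise ValueError(
                f"ROI {roi.roi_id!r} rect out of image bounds at frame {f}"
            )
        out[f] = frames[f, r0 : r0 + hh, c0 : c0 + ww].mean()
    return out


def subtract_background(
    cell: np.ndarray, background: np.ndarray, clip_negative: bool = False
) -> np.ndarray:
    """Elementwise cell minus background MPI.

    Negative values are kept unless ``clip_negative`` is set; the
    correction stage requires the unclipped values.
    """
    cell = np.asarray(cell, dtype=float)
    background = np.asarray(background, dtype=float)
    if cell.shape != background.shape:
        raise ValueError(
            f"length mismatch: cell has {cell.shape}, background {background.shape}"
        )
    out = cell - background
    if clip_negative:
        out = np.clip(out, 0.0, None)
    return out


def _id_distance(a: str, b: str) -> float:
    try:
        return abs(int(a) - int(b))
    except (TypeError, ValueError):
        return float(a != b)


def pair_rois(tracks: Sequence[RoiTrack]) -> Dict[str, str]:
    """Pair every cell ROI with its same-channel background ROI.

    When a channel has several background ROIs the one with the nearest id
    (numeric distance when ids are numeric, else first in sorted order) is
    chosen.  Raises ``ValueError`` naming any channel that has cell ROIs
    but no background ROI.
    """
    cells = [t for t in tracks if t.role == "cell"]
    backgrounds = [t for t in tracks if t.role == "background"]
    pairing: Dict[str, str] = {}
    missing = []
    for cell in cells:
        candidates = [b for b in backgrounds if b.channel == cell.channel]
        if not candidates:
            missing.append(cell.channel)
            continue
        best = min(
            sorted(candidates, key=lambda b: str(b.roi_id)),
            key=lambda b: _id_distance(cell.roi_id, b.roi_id),
        )
        pairing[cell.roi_id] = best.roi_id
    if missing:
        raise ValueError(
            "no background ROI for channel(s): " + ", ".join(sorted(set(missing)))
        )
    return pairing


def extract_traces(
    stack: DualChannelStack, tracks: Sequence[RoiTrack]
) -> FluorescenceTraceSet:
    """Full extraction stage: MPI for every ROI, then background subtraction
    for every cell ROI using its paired background."""
    raw = {t.roi_id: extract_mpi(stack, t) for t in tracks}
    pairing = pair_rois(tracks)
    bg_sub = {
        cell_id: subtract_background(raw[cell_id], raw[bg_id])
        for cell_id, bg_id in pairing.items()
    }
    return FluorescenceTraceSet(
        times=stack.times, raw_mpi=raw, bg_subtracted=bg_sub, pairing=pairing
    )
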