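"""Core containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Channel axis layout of a :class:`DualChannelStack`.
GREEN = 0
RED = 1

CHANNEL_INDEX = {"green": GREEN, "red": RED}
CHANNEL_NAMES = {GREEN: "green", RED: "red"}


@dataclass
class DualChannelStack:
    """A two-channel time-lapse recording.

    Parameters
    ----------
    data:
        Float array of shape ``(n_frames, height, width, 2)``.  Channel 0 is
        the green (calcium reporter) channel, channel 1 the red
        (calcium-insensitive reference) channel.  Intensities are arbitrary
        units; integer TIFF data is promoted to float on load.
    frame_rate:
        Acquisition rate in frames per second.
    """

    data: np.ndarray
    frame_rate: float = 30.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4 or self.data.shape[-1] != 2:
            raise ValueError(
                "stack data must have shape (n_frames, height, width, 2), "
                f"got {self.data.shape}"
            )
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def times(self) -> np.ndarray:
        """Frame times in seconds, first frame at t = 0."""
        return np.arange(self.n_frames) / self.frame_rate

    def channel(self, name_or_index) -> np.ndarray:
        """Return one channel as a ``(n_frames, height, width)`` array."""
        idx = CHANNEL_INDEX.get(name_or_index, name_or_index)
        return self.data[..., idx]
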