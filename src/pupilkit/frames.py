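"""Core acquisition data types.

A :class:`RawFrame` is the unit of acquisition: one 8-bit grayscale image of
one eye (or of a validation phantom standing in for an eye), together with
the eye label, the acquisition timestamp and the frame index within its
sequence.  A single camera images both eyes in alternation, so a recording
is a stream of frames whose eye labels alternate; demultiplexing into
per-eye streams lives in :mod:`pupilkit.timeseries`.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["Eye", "RawFrame", "MIN_FRAME_SIDE"]

#: Smallest frame side length accepted by the acquisition types.  The
#: instrument records 1024x1024; anything below 64 px cannot hold a
#: plausibly sized pupil plus margin.
MIN_FRAME_SIDE = 64


class Eye(str, enum.Enum):
    """Which eye a frame or trace belongs to."""

    LEFT = "left"
    RIGHT = "right"
    UNKNOWN = "unknown"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass
class RawFrame:
    """One 8-bit grayscale frame with acquisition metadata.

    Parameters
    ----------
    pixels
        2-D ``uint8`` intensity array, at least 64x64.
    eye
        Eye label; ``Eye.UNKNOWN`` when the source carries no label.
    timestamp_s
        Acquisition time in seconds from the start of the recording.
    frame_index
        Position of the frame in its sequence.
    """

    pixels: np.ndarray
    eye: Eye = Eye.UNKNOWN
    timestamp_s: float = 0.0
    frame_index: int = 0

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError(f"frame must be 2-D, got shape {px.shape}")
        if min(px.shape) < MIN_FRAME_SIDE:
            raise ValueError(
                f"frame sides must be >= {MIN_FRAME_SIDE}, got {px.shape}"
            )
        if px.dtype != np.uint8:
            if np.issubdtype(px.dtype, np.integer) and px.min() >= 0 and px.max() <= 255:
                px = px.astype(np.uint8)
            else:
                raise ValueError("frame pixels must be 8-bit (uint8 or 0..255 ints)")
        self.pixels = px
        self.eye = Eye(self.eye)
        self.frame_index = int(self.frame_index)
        self.timestamp_s = float(self.timestamp_s)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    def with_pixels(self, pixels: np.ndarray) -> "RawFrame":
        """Copy of this frame with new pixel data, metadata preserved."""
        return replace(self, pixels=pixels)
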