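"""Per-eye pupil dynamic waveforms.

Frame-by-frame ellipse results become a :class:`PupilTrace`: the
time-varying pupil parameters of one eye, stored as a tidy table.  This
module demultiplexes the alternating left/right frame stream of the
single-camera acquisition, repairs blink artifacts by neighbor averaging,
and converts pixel units to millimeters with a calibration scale obtained
from phantom measurements.

The per-eye sampling rate is bounded by 75 Hz, the acquisition limit of
the instrument at full resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .ellipse import PupilEllipse
from .frames import Eye, RawFrame

__all__ = [
    "CalibrationScale",
    "PupilTrace",
    "demux_binocular",
    "remove_blinks",
    "to_mm",
    "to_px",
    "MAX_RATE_HZ",
]

#: Per-eye sampling-rate ceiling of the acquisition chain (Hz).
MAX_RATE_HZ = 75.0

#: Column schema shared with the CSV trace format.
TRACE_COLUMNS = [
    "frame_index",
    "timestamp_s",
    "eye",
    "center_x",
    "center_y",
    "major_px",
    "minor_px",
    "orientation_rad",
    "valid",
    "fail_reason",
]


class NoValidSamplesError(ValueError):
    """A trace contains no valid pupil samples."""


@dataclass(frozen=True)
class CalibrationScale:
    """Linear scale of the imaging chain, millimeters per pixel."""

    mm_per_px: float

    def __post_init__(self) -> None:
        if not self.mm_per_px > 0:
            raise ValueError("mm_per_px must be positive")


@dataclass
class PupilTrace:
    """Time series of pupil parameters for one eye.

    ``data`` holds one row per frame with the shared trace schema
    (`frame_index, timestamp_s, eye, center_x, center_y, major_px,
    minor_px, orientation_rad, valid, fail_reason`).  Geometric columns of
    invalid rows are NaN.  ``unit`` is ``"px"`` or ``"mm"``; axis/center
    columns keep their names in either unit, with ``unit`` as the
    authority.
    """

    eye: Eye
    data: pd.DataFrame
    sampling_rate_hz: float = MAX_RATE_HZ
    unit: str = "px"
    scale: CalibrationScale | None = None
    _px_data: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.eye = Eye(self.eye)
        if not 0 < self.sampling_rate_hz <= MAX_RATE_HZ:
            raise ValueError(
                f"per-eye sampling rate must be in (0, {MAX_RATE_HZ}] Hz,"
                f" got {self.sampling_rate_hz}"
            )
        if self.unit not in ("px", "mm"):
            raise ValueError("unit must be 'px' or 'mm'")
        missing = [c for c in TRACE_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"trace missing columns: {missing}")
        t = self.data["timestamp_s"].to_numpy(float)
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("timestamps must be strictly increasing")

    # -- constructors -----------------------------------------------------
    @classmethod
    def from_ellipses(
        cls,
        eye: Eye,
        samples: list[tuple[float, PupilEllipse]],
        sampling_rate_hz: float = MAX_RATE_HZ,
        frame_indices: list[int] | None = None,
    ) -> "PupilTrace":
        rows = []
        for k, (t, e) in enumerate(samples):
            idx = frame_indices[k] if frame_indices is not None else k
            if e.valid:
                rows.append(
                    (idx, t, Eye(eye).value, e.center[0], e.center[1], e.major_axis_px,
                     e.minor_axis_px, e.orientation_rad, True, "")
                )
            else:
                rows.append(
                    (idx, t, Eye(eye).value, np.nan, np.nan, np.nan, np.nan, np.nan,
                     False, e.fail_reason or "")
                )
        df = pd.DataFrame(rows, columns=TRACE_COLUMNS)
        return cls(eye=Eye(eye), data=df, sampling_rate_hz=sampling_rate_hz)

    @classmethod
    def from_frames(
        cls,
        eye: Eye,
        frames: list[RawFrame],
        sampling_rate_hz: float = MAX_RATE_HZ,
        **segment_kwargs,
    ) -> "PupilTrace":
        """Segment every frame and assemble the trace."""
        from .segmentation import segment_pupil

        samples = [(f.timestamp_s, segment_pupil(f, **segment_kwargs)) for f in frames]
        return cls.from_ellipses(
            eye, samples, sampling_rate_hz, frame_indices=[f.frame_index for f in frames]
        )

    def __len__(self) -> int:
        return len(self.data)

    @property
    def timestamps(self) -> np.ndarray:
        return self.data["timestamp_s"].to_numpy(float)

    @property
    def major_px(self) -> np.ndarray:
        return self.data["major_px"].to_numpy(float)

    @property
    def valid(self) -> np.ndarray:
        return self.data["valid"].to_numpy(bool)


def demux_binocular(
    frames: list[RawFrame], phase: str | None = None
) -> tuple[list[RawFrame], list[RawFrame]]:
    """Split an alternating binocular frame stream into per-eye streams.

    Eye assignment uses the frames' own labels when present.  Unlabeled
    streams require an explicit ``phase`` (``"even-left"`` or
    ``"even-right"``): assignment by frame-index parity, never inferred
    from image content.  Every frame goes to exactly one eye, so
    ``len(left) + len(right) == len(frames)``.

    Raises ``ValueError`` listing the offending frame indices when labels
    are missing and no phase is given.
    """
    left: list[RawFrame] = []
    right: list[RawFrame] = []
    unresolved: list[int] = []
    for pos, f in enumerate(frames):
        eye = f.eye
        if eye == Eye.UNKNOWN:
            if phase == "even-left":
                eye = Eye.LEFT if f.frame_index % 2 == 0 else Eye.RIGHT
            elif phase == "even-right":
                eye = Eye.RIGHT if f.frame_index % 2 == 0 else Eye.LEFT
            else:
                unresolved.append(pos)
                continue
        (left if eye == Eye.LEFT else right).append(f)
    if unresolved:
        raise ValueError(
            f"frames without eye label and no demux phase given, at indices {unresolved}"
        )
    return left, right


def _window_mean_std(x: np.ndarray, valid: np.ndarray, half: int) -> tuple[np.ndarray, np.ndarray]:
    """Centered moving mean/SD over valid samples only (window 2*half+1)."""
    n = len(x)
    mean = np.full(n, np.nan)
    sd = np.full(n, np.nan)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        sel = valid[lo:hi]
        if sel.sum() >= 2:
            vals = x[lo:hi][sel]
            mean[i] = vals.mean()
            sd[i] = vals.std(ddof=1)
    return mean, sd


#: Absolute floor on the local SD used by the outlier guard, in trace
#: units; prevents a flat trace from flagging numerical dust as blinks.
_SD_FLOOR = 0.01


def remove_blinks(trace: PupilTrace, window_s: float = 1.0) -> PupilTrace:
    """Repair blink artifacts by neighbor averaging.

    Two kinds of samples are treated as blink-contaminated: samples the
    segmentation already marked invalid, and valid samples whose major
    axis deviates from the centered moving average (window ``window_s``)
    by more than 3 local standard deviations.  Each contaminated sample is
    replaced by the mean of the nearest valid sample before and after it
    within ``window_s`` (one-sided when only one exists; nearest valid
    overall for leading/trailing gaps).  The output contains no invalid
    samples.  A clean trace is returned unchanged, and the operation is
    idempotent.

    Raises :class:`NoValidSamplesError` when the whole trace is invalid.
    """
    if len(trace) == 0:
        raise NoValidSamplesError("no valid pupil samples: empty trace")
    df = trace.data.copy()
    t = df["timestamp_s"].to_numpy(float)
    valid = df["valid"].to_numpy(bool)
    if not valid.any():
        raise NoValidSamplesError("no valid pupil samples")

    major = df["major_px"].to_numpy(float)
    half = max(1, round(window_s * trace.sampling_rate_hz / 2.0))
    mean, sd = _window_mean_std(major, valid, half)
    with np.errstate(invalid="ignore"):
        outlier = valid & np.isfinite(mean) & (
            np.abs(major - mean) > 3.0 * np.maximum(sd, _SD_FLOOR)
        )
    good = valid & ~outlier
    if not good.any():
        raise NoValidSamplesError("no valid pupil samples after outlier screening")
    bad_idx = np.flatnonzero(~good)
    good_idx = np.flatnonzero(good)

    num_cols = ["center_x", "center_y", "major_px", "minor_px", "orientation_rad"]
    vals = {c: df[c].to_numpy(float) for c in num_cols}
    for i in bad_idx:
        pos = np.searchsorted(good_idx, i)
        prev = good_idx[pos - 1] if pos > 0 else None
        nxt = good_idx[pos] if pos < len(good_idx) else None
        if prev is not None and t[i] - t[prev] > window_s:
            prev = None
        if nxt is not None and t[nxt] - t[i] > window_s:
            nxt = None
        if prev is None and nxt is None:
            # gap wider than the window: fall back to the nearest valid sample
            nearest = good_idx[np.argmin(np.abs(t[good_idx] - t[i]))]
            donors = [nearest]
        else:
            donors = [d for d in (prev, nxt) if d is not None]
        for c in num_cols:
            vals[c][i] = np.mean([vals[c][d] for d in donors])
    for c in num_cols:
        df[c] = vals[c]
    df["valid"] = True
    df["fail_reason"] = ""
    return replace(trace, data=df, _px_data=None)


def to_mm(trace: PupilTrace, scale: CalibrationScale | None = None) -> PupilTrace:
    """Convert a pixel-unit trace to millimeters.

    Axis lengths and center coordinates are multiplied by ``mm_per_px``.
    The returned trace remembers the exact pixel-unit table, so
    :func:`to_px` restores it bit-identically.
    """
    scale = scale or trace.scale
    if scale is None:
        raise ValueError("no calibration scale given or attached to the trace")
    if trace.unit == "mm":
        raise ValueError("trace is already in millimeters")
    df = trace.data.copy()
    for c in ("center_x", "center_y", "major_px", "minor_px"):
        df[c] = df[c] * scale.mm_per_px
    return replace(trace, data=df, unit="mm", scale=scale, _px_data=trace.data)


def to_px(trace: PupilTrace) -> PupilTrace:
    """Invert :func:`to_mm`.

    Uses the remembered pixel table when present (exact inverse);
    otherwise divides by the attached scale.
    """
    if trace.unit == "px":
        return trace
    if trace._px_data is not None:
        return replace(trace, data=trace._px_data, unit="px", _px_data=None)
    if trace.scale is None:
        raise ValueError("trace carries no scale to invert")
    df = trace.data.copy()
    for c in ("center_x", "center_y", "major_px", "minor_px"):
        df[c] = df[c] / trace.scale.mm_per_px
    return replace(trace, data=df, unit="px", _px_data=None)
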