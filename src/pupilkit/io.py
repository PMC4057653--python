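"""Image-sequence and trace I/O.

Frame sequences are stored as 8-bit grayscale BMP or PNG files named
``<prefix>_<eye>_<index>.<ext>`` with the index zero-padded to five
digits (``run_left_00042.bmp``).  Traces use the shared CSV schema of
:mod:`pupilkit.timeseries`, always with a '.' decimal separator.
"""

from __future__ import annotations

import glob as globmod
import re
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .frames import Eye, RawFrame
from .timeseries import MAX_RATE_HZ, TRACE_COLUMNS, PupilTrace

__all__ = ["read_frames", "write_frames", "read_trace", "write_trace"]

_NAME_RE = re.compile(r"^(?P<prefix>.+)_(?P<eye>left|right|unknown)_(?P<index>\d+)$")


def frame_filename(prefix: str, eye: Eye, index: int, ext: str = "bmp") -> str:
    return f"{prefix}_{Eye(eye).value}_{index:05d}.{ext}"


def write_frames(
    frames: list[RawFrame], directory: str | Path, prefix: str = "frame", ext: str = "bmp"
) -> list[Path]:
    """Write frames as 8-bit grayscale images under ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for f in frames:
        p = directory / frame_filename(prefix, f.eye, f.frame_index, ext)
        iio.imwrite(p, f.pixels)
        paths.append(p)
    return paths


def read_frames(
    pattern: str | Path,
    frame_rate_hz: float = MAX_RATE_HZ * 2,
) -> list[RawFrame]:
    """Read an image sequence matching a glob pattern or directory.

    Frames are ordered by the index parsed from the canonical
    ``<prefix>_<eye>_<index>`` name (falling back to lexical order), eye
    labels come from the name, and timestamps are synthesized from the
    frame rate when absent (index / rate, frame 0 at t=0).  Mixed image
    sizes are an error; non-grayscale images are converted with a
    warning.
    """
    pattern = str(pattern)
    if Path(pattern).is_dir():
        pattern = str(Path(pattern) / "*")
    paths = [Path(p) for p in sorted(globmod.glob(pattern))]
    paths = [p for p in paths if p.suffix.lower() in (".bmp", ".png")]
    if not paths:
        raise FileNotFoundError(f"no frames found matching {pattern!r}")

    entries = []
    for p in paths:
        m = _NAME_RE.match(p.stem)
        if m:
            entries.append((int(m.group("index")), Eye(m.group("eye")), p))
        else:
            entries.append((len(entries), Eye.UNKNOWN, p))
    entries.sort(key=lambda e: e[0])

    frames = []
    shape = None
    for index, eye, p in entries:
        px = iio.imread(p)
        if px.ndim == 3:
            import warnings

            warnings.warn(f"{p.name}: not grayscale, converting by channel mean")
            px = np.rint(px[..., :3].mean(axis=-1)).astype(np.uint8)
        if shape is None:
            shape = px.shape
        elif px.shape != shape:
            raise ValueError(f"mixed frame dimensions: {shape} vs {px.shape} ({p.name})")
        frames.append(
            RawFrame(px, eye=eye, timestamp_s=index / frame_rate_hz, frame_index=index)
        )
    return frames


def write_trace(trace: PupilTrace, path: str | Path) -> Path:
    """Write a trace as CSV using the shared column schema."""
    path = Path(path)
    df = trace.data.loc[:, TRACE_COLUMNS]
    df.to_csv(path, index=False)
    return path


def read_trace(
    path: str | Path, sampling_rate_hz: float = MAX_RATE_HZ, unit: str = "px"
) -> PupilTrace:
    """Read a trace CSV back into a :class:`PupilTrace`."""
    df = pd.read_csv(path, dtype={"fail_reason": str}, keep_default_na=False)
    df["fail_reason"] = df["fail_reason"].astype(str)
    for c in ("center_x", "center_y", "major_px", "minor_px", "orientation_rad"):
        df[c] = pd.to_numeric(df[c], errors="coerce")
    df["valid"] = df["valid"].astype(str).str.lower().isin(("true", "1"))
    df["frame_index"] = df["frame_index"].astype(int)
    df["timestamp_s"] = df["timestamp_s"].astype(float)
    eyes = set(df["eye"]) - {""}
    eye = Eye(eyes.pop()) if len(eyes) == 1 else Eye.UNKNOWN
    return PupilTrace(eye=eye, data=df, sampling_rate_hz=sampling_rate_hz, unit=unit)
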