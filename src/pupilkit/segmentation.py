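"""Frame-by-frame pupil segmentation.

The analysis pipeline runs five stages on each grayscale frame:

1. 5x5 median smoothing (suppresses sensor noise and small specks),
2. global thresholding at the mean image intensity (pupil = dark class;
   bright corneal reflections inside the pupil drop out here as holes),
3. morphological closing with a disk, hole filling, and selection of the
   largest connected component (restores the pupillary region to a single
   solid object),
4. inner-boundary extraction (component pixels with a 4-neighbor outside),
5. direct least-squares ellipse fitting of the boundary coordinates.

The result is a :class:`~pupilkit.ellipse.PupilEllipse` per frame; any
stage failure (all-bright frame, blink, degenerate boundary) yields an
*invalid* result with a reason rather than an exception, so a sequence is
never interrupted by a bad frame.

Coordinate convention: pixel ``(row i, col j)`` has center
``(x, y) = (j + 0.5, i + 0.5)`` in continuous image coordinates.  Boundary
points and fitted centers live in these continuous coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from ._filters import median_filter_u8
from .ellipse import PupilEllipse, fit_ellipse
from .frames import RawFrame

__all__ = [
    "PupilEllipse",
    "SegmentationStages",
    "median_smooth",
    "compute_threshold",
    "binarize",
    "close_and_fill",
    "extract_boundary",
    "segment_pupil",
    "closing_radius_for",
]

#: Disk radius for morphological closing at the native 1024x1024 scale.
#: Large enough to bridge notches cut by IR reflection spots on the pupil
#: rim, small enough not to distort a 119-px pupil.
CLOSING_RADIUS_1024 = 5

_CROSS = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], bool)


class NoPupilError(ValueError):
    """Raised by stages that require a candidate pupil region."""


@dataclass
class SegmentationStages:
    """Optional per-stage diagnostics retained by :func:`segment_pupil`."""

    smoothed: np.ndarray | None = None
    threshold: float | None = None
    mask_raw: np.ndarray | None = None
    mask_filled: np.ndarray | None = None
    boundary: np.ndarray | None = None


def _pixels(frame: RawFrame | np.ndarray) -> np.ndarray:
    px = frame.pixels if isinstance(frame, RawFrame) else np.asarray(frame)
    if px.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    return px


def median_smooth(frame: RawFrame | np.ndarray, window: int = 5):
    """Median smoothing with an odd ``window`` (default 5x5), edge-replicated.

    Accepts a :class:`RawFrame` (metadata preserved) or a bare ``uint8``
    array (array returned).
    """
    if window % 2 == 0 or window < 3:
        raise ValueError(f"window must be odd and >= 3, got {window}")
    px = _pixels(frame)
    out = median_filter_u8(px, window)
    if isinstance(frame, RawFrame):
        return frame.with_pixels(out)
    return out


def compute_threshold(frame: RawFrame | np.ndarray) -> float:
    """Mean image intensity, computed from the 256-bin histogram.

    The mean serves as the global binarization threshold: pixels strictly
    below it are pupil candidates.  Under stable illumination the mean is
    nearly constant across a sequence, which keeps the binarization stable
    frame to frame.
    """
    px = _pixels(frame)
    if px.size == 0:
        raise ValueError("empty frame")
    hist = np.bincount(px.ravel(), minlength=256)
    return float((hist * np.arange(256)).sum() / px.size)


def binarize(frame: RawFrame | np.ndarray, threshold: float) -> np.ndarray:
    """Boolean mask of pixels strictly below ``threshold`` (candidate pupil).

    Bright artifacts (e.g. IR reflections) inside the pupil fall above the
    threshold and appear as holes in the mask at this stage.
    """
    if not 0 <= threshold <= 255:
        raise ValueError(f"threshold must be in [0, 255], got {threshold}")
    return _pixels(frame) < threshold


def closing_radius_for(shape: tuple[int, int]) -> int:
    """Closing-disk radius scaled from the native 1024-px frame size."""
    return max(1, round(CLOSING_RADIUS_1024 * min(shape) / 1024))


def _disk_closing(mask: np.ndarray, radius: int) -> np.ndarray:
    """Binary closing with a Euclidean disk of ``radius`` pixels.

    Implemented with two distance transforms on a bounding-box crop; the
    pixel set is identical to footprint-based closing with
    ``{(dx, dy): dx^2 + dy^2 <= r^2}``, and cropping to the global bounding
    box plus ``radius + 1`` margin is exact because closing is local.
    """
    rows = np.flatnonzero(mask.any(axis=1))
    if rows.size == 0:
        return mask.copy()
    cols = np.flatnonzero(mask.any(axis=0))
    pad = radius + 1
    r0, r1 = max(rows[0] - pad, 0), min(rows[-1] + pad + 1, mask.shape[0])
    c0, c1 = max(cols[0] - pad, 0), min(cols[-1] + pad + 1, mask.shape[1])
    sub = mask[r0:r1, c0:c1]
    dilated = ndi.distance_transform_edt(~sub) <= radius
    closed = ndi.distance_transform_edt(dilated) > radius
    out = mask.copy()
    out[r0:r1, c0:c1] = closed
    return out


def close_and_fill(mask: np.ndarray, radius: int | None = None) -> np.ndarray:
    """Close, fill and isolate the pupillary region.

    Morphological closing with a disk structuring element bridges boundary
    notches; hole filling turns any enclosed false region solid (the
    reflection holes left by thresholding); finally only the largest
    connected component is retained, discarding stray dark specks.

    Raises :class:`NoPupilError` on an empty mask.
    """
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise NoPupilError("no pupil found: empty binary mask")
    if radius is None:
        radius = closing_radius_for(mask.shape)
    closed = _disk_closing(mask, radius)
    filled = ndi.binary_fill_holes(closed)
    labels, n = ndi.label(filled)
    if n > 1:
        sizes = np.bincount(labels.ravel())
        sizes[0] = 0
        filled = labels == sizes.argmax()
    return filled


def extract_boundary(mask: np.ndarray) -> np.ndarray:
    """Inner-boundary pixel centers of a single-component mask.

    A boundary pixel is a component pixel with at least one 4-neighbor
    outside the component (image border counts as outside).  Returns an
    ``(n, 2)`` array of ``(x, y) = (j + 0.5, i + 0.5)`` coordinates.
    """
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise NoPupilError("no pupil found: empty mask")
    interior = ndi.binary_erosion(mask, structure=_CROSS, border_value=0)
    bi, bj = np.nonzero(mask & ~interior)
    return np.column_stack([bj + 0.5, bi + 0.5]).astype(float)


def segment_pupil(
    frame: RawFrame | np.ndarray,
    window: int = 5,
    closing_radius: int | None = None,
    stages: SegmentationStages | None = None,
) -> PupilEllipse:
    """Run the full pupil analysis pipeline on one frame.

    Parameters
    ----------
    frame
        8-bit grayscale frame (or bare array).
    window
        Median smoothing window (odd, default 5).
    closing_radius
        Closing-disk radius; default scales the native radius of 5 px at
        1024x1024 with the frame size.
    stages
        Pass a :class:`SegmentationStages` to retain intermediate products
        for diagnostics.

    Returns
    -------
    PupilEllipse
        Valid fit, or an invalid result whose ``fail_reason`` explains the
        failure (e.g. ``"no pupil found: empty binary mask"`` on an
        all-bright or blink frame).  Exceptions are reserved for misuse
        (bad window, non-image input), never for image content.
    """
    px = _pixels(frame)
    smoothed = median_filter_u8(px, window) if window else px
    threshold = compute_threshold(smoothed)
    mask = smoothed < threshold
    if stages is not None:
        stages.smoothed = smoothed
        stages.threshold = threshold
        stages.mask_raw = mask
    try:
        filled = close_and_fill(mask, radius=closing_radius)
        boundary = extract_boundary(filled)
    except NoPupilError as exc:
        return PupilEllipse.invalid(str(exc))
    if stages is not None:
        stages.mask_filled = filled
        stages.boundary = boundary
    return fit_ellipse(boundary)
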