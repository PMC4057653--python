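"""Least-squares ellipse fitting.

The pupil boundary is summarized by its *equivalent ellipse*: the conic
``A x^2 + B xy + C y^2 + D x + E y + F = 0`` minimizing the algebraic
residual over the boundary points, subject to the ellipse constraint
``4AC - B^2 = 1``.  The constrained problem is solved directly (no
initialization, no iteration) via the numerically stable block
decomposition of the scatter matrix, with the data centered on its mean
beforehand; the conic is then converted to geometric parameters
(center, full axis lengths, major-axis orientation).

A slower geometric fit that minimizes true point-to-ellipse distance is
deliberately *not* provided here; it exists only as an independent oracle
in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PupilEllipse", "fit_ellipse", "ellipse_points"]


@dataclass
class PupilEllipse:
    """Pupil parameters: the equivalent ellipse of the pupil boundary.

    Axis lengths are *full* lengths (twice the semi-axes), in pixels
    unless the owning trace has been converted to millimeters.
    ``orientation_rad`` is the angle of the major axis against the image
    x-axis, normalized to (-pi/2, pi/2].  When ``valid`` is False the
    geometric fields are ``None`` (missing, never zero) and
    ``fail_reason`` says why.
    """

    center: tuple[float, float] | None = None
    orientation_rad: float | None = None
    major_axis_px: float | None = None
    minor_axis_px: float | None = None
    valid: bool = True
    fail_reason: str | None = None

    def __post_init__(self) -> None:
        if self.valid:
            if self.center is None or self.major_axis_px is None or self.minor_axis_px is None:
                raise ValueError("valid ellipse must carry center and both axes")
            if not (self.major_axis_px >= self.minor_axis_px >= 0):
                raise ValueError("major axis must be >= minor axis >= 0")

    @classmethod
    def invalid(cls, reason: str) -> "PupilEllipse":
        return cls(valid=False, fail_reason=reason)


def _normalize_orientation(theta: float) -> float:
    """Fold an angle into (-pi/2, pi/2]."""
    theta = (theta + np.pi / 2) % np.pi - np.pi / 2
    if theta <= -np.pi / 2:  # map the open end
        theta += np.pi
    if theta == -0.0:
        theta = 0.0
    return float(theta)


def _conic_to_geometric(coeffs: np.ndarray) -> tuple[tuple[float, float], float, float, float]:
    """Convert conic coefficients (A,B,C,D,E,F) to (center, major, minor, theta).

    Raises ``ValueError`` if the conic is not a real ellipse.
    """
    A, B, C, D, E, F = (float(c) for c in coeffs)
    M = np.array([[A, B / 2.0], [B / 2.0, C]])
    detM = A * C - B * B / 4.0
    if detM <= 0:
        raise ValueError("conic is not an ellipse")
    M0 = np.array(
        [
            [F, D / 2.0, E / 2.0],
            [D / 2.0, A, B / 2.0],
            [E / 2.0, B / 2.0, C],
        ]
    )
    detM0 = float(np.linalg.det(M0))
    cx, cy = np.linalg.solve(2.0 * M, -np.array([D, E]))
    lam, vec = np.linalg.eigh(M)
    with np.errstate(invalid="raise"):
        try:
            semi = np.sqrt(-detM0 / (detM * lam))
        except FloatingPointError as exc:
            raise ValueError("degenerate ellipse (non-positive axis)") from exc
    imaj = int(np.argmax(semi))  # the conic's overall sign decides which slot is major
    major, minor = 2.0 * semi[imaj], 2.0 * semi[1 - imaj]
    vx, vy = vec[:, imaj]
    theta = _normalize_orientation(float(np.arctan2(vy, vx)))
    return (float(cx), float(cy)), float(major), float(minor), theta


def fit_ellipse(points: np.ndarray) -> PupilEllipse:
    """Direct algebraic least-squares ellipse fit.

    Parameters
    ----------
    points
        ``(n, 2)`` array-like of ``(x, y)`` boundary coordinates, ``n >= 5``
        and not collinear.

    Returns
    -------
    PupilEllipse
        Valid fit, or an invalid result with ``fail_reason`` set when the
        input is too small or degenerate.  Never raises for degeneracy, so
        sequence processing can carry on past bad frames.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError(f"points must be (n, 2), got {pts.shape}")
    if pts.shape[0] < 5:
        return PupilEllipse.invalid(f"need >= 5 points, got {pts.shape[0]}")

    x = pts[:, 0]
    y = pts[:, 1]
    xm, ym = x.mean(), y.mean()
    xs, ys = x - xm, y - ym

    D1 = np.column_stack([xs * xs, xs * ys, ys * ys])
    D2 = np.column_stack([xs, ys, np.ones_like(xs)])
    S1 = D1.T @ D1
    S2 = D1.T @ D2
    S3 = D2.T @ D2
    try:
        T = -np.linalg.solve(S3, S2.T)
    except np.linalg.LinAlgError:
        return PupilEllipse.invalid("degenerate point configuration")
    M = S1 + S2 @ T
    # Premultiply by inv(constraint matrix): rows reordered/scaled.
    M = np.array([M[2] / 2.0, -M[1], M[0] / 2.0])
    try:
        eigval, eigvec = np.linalg.eig(M)
    except np.linalg.LinAlgError:  # pragma: no cover - eig rarely fails
        return PupilEllipse.invalid("eigen decomposition failed")
    cond = 4.0 * eigvec[0] * eigvec[2] - eigvec[1] ** 2
    ok = np.isreal(eigval) & (cond > 0)
    if not ok.any():
        return PupilEllipse.invalid("no ellipse solution (collinear or degenerate points)")
    a1 = np.real(eigvec[:, ok][:, 0])
    coeffs = np.concatenate([a1, T @ a1])
    try:
        (cx, cy), major, minor, theta = _conic_to_geometric(coeffs)
    except ValueError as exc:
        return PupilEllipse.invalid(str(exc))
    return PupilEllipse(
        center=(cx + xm, cy + ym),
        orientation_rad=theta,
        major_axis_px=major,
        minor_axis_px=minor,
    )


def ellipse_points(
    center: tuple[float, float],
    major: float,
    minor: float,
    theta: float,
    n: int = 360,
    angles: np.ndarray | None = None,
) -> np.ndarray:
    """Sample ``(x, y)`` points on an analytic ellipse (full axis lengths)."""
    t = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False) if angles is None else np.asarray(angles)
    ct, st = np.cos(theta), np.sin(theta)
    px = center[0] + (major / 2.0) * np.cos(t) * ct - (minor / 2.0) * np.sin(t) * st
    py = center[1] + (major / 2.0) * np.cos(t) * st + (minor / 2.0) * np.sin(t) * ct
    return np.column_stack([px, py])
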