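"""Independent oracles for the test suite.

Deliberately brute-force implementations, kept free of any code shared
with the package paths they check.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import least_squares


def brute_force_median(img: np.ndarray, window: int) -> np.ndarray:
    """Per-pixel sort-and-pick-middle median with edge replication."""
    r = window // 2
    h, w = img.shape
    padded = np.pad(img, r, mode="edge")
    out = np.empty_like(img)
    for i in range(h):
        for j in range(w):
            block = padded[i : i + window, j : j + window].ravel()
            out[i, j] = np.sort(block)[len(block) // 2]
    return out


def count_pixel_centers_inside(
    cx: float, cy: float, ax_full: float, ay_full: float, width: int, height: int
) -> int:
    """Count pixel centers (j+0.5, i+0.5) inside the analytic ellipse."""
    n = 0
    for i in range(height):
        y = i + 0.5
        for j in range(width):
            x = j + 0.5
            if ((x - cx) / (ax_full / 2)) ** 2 + ((y - cy) / (ay_full / 2)) ** 2 <= 1.0:
                n += 1
    return n


def _point_ellipse_distances(
    points: np.ndarray, cx: float, cy: float, a: float, b: float, theta: float, m: int = 4096
) -> np.ndarray:
    """Distance from each point to a densely sampled ellipse outline."""
    t = np.linspace(0, 2 * np.pi, m, endpoint=False)
    ct, st = np.cos(theta), np.sin(theta)
    ex = cx + a * np.cos(t) * ct - b * np.sin(t) * st
    ey = cy + a * np.cos(t) * st + b * np.sin(t) * ct
    d = np.hypot(points[:, 0, None] - ex[None, :], points[:, 1, None] - ey[None, :])
    return d.min(axis=1)


def geometric_ellipse_fit(
    points: np.ndarray,
    init: tuple[float, float, float, float, float],
) -> tuple[float, float, float, float, float]:
    """Least-squares fit minimizing true point-to-outline distance.

    ``init``/return: (cx, cy, semi_a, semi_b, theta).  Seeded at the true
    parameters; serves as the geometric-distance oracle for the algebraic
    fitter.
    """
    pts = np.asarray(points, float)

    def resid(p):
        return _point_ellipse_distances(pts, *p)

    sol = least_squares(resid, x0=np.asarray(init, float), method="lm")
    return tuple(sol.x)
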