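"""Fast exact rank filtering for 8-bit images.

The default 5x5 median smoothing runs on every frame of every sequence, so
its cost dominates batch processing.  For ``uint8`` input we use a sliding
256-bin histogram with a remembered median (Huang's algorithm), compiled
with numba when available; it is bit-identical to
``scipy.ndimage.median_filter(..., mode="nearest")``, which remains the
fallback implementation.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi

try:  # optional acceleration
    import numba

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is an optional extra
    _HAVE_NUMBA = False


def _median_u8_py(a: np.ndarray, r: int) -> np.ndarray:
    """Sliding-histogram median, edge-replicated borders.

    Plain-Python reference of the numba kernel; only used indirectly (the
    numba path compiles this same logic).
    """
    h, w = a.shape
    win = 2 * r + 1
    half = (win * win) // 2 + 1  # 1-based rank of the median element
    out = np.empty_like(a)
    hist = np.zeros(256, np.int32)
    for i in range(h):
        hist[:] = 0
        for dy in range(-r, r + 1):
            yy = min(max(i + dy, 0), h - 1)
            for dx in range(-r, r + 1):
                xx = min(max(dx, 0), w - 1)
                hist[a[yy, xx]] += 1
        c = 0
        mdn = 0
        for v in range(256):
            c += hist[v]
            if c >= half:
                mdn = v
                break
        ltm = 0
        for v in range(mdn):
            ltm += hist[v]
        out[i, 0] = mdn
        for j in range(1, w):
            for dy in range(-r, r + 1):
                yy = min(max(i + dy, 0), h - 1)
                xo = min(max(j - r - 1, 0), w - 1)
                xn = min(max(j + r, 0), w - 1)
                vo = a[yy, xo]
                vn = a[yy, xn]
                hist[vo] -= 1
                if vo < mdn:
                    ltm -= 1
                hist[vn] += 1
                if vn < mdn:
                    ltm += 1
            if ltm >= half:
                while ltm >= half:
                    mdn -= 1
                    ltm -= hist[mdn]
            else:
                while ltm + hist[mdn] < half:
                    ltm += hist[mdn]
                    mdn += 1
            out[i, j] = mdn
    return out


if _HAVE_NUMBA:
    _median_u8_jit = numba.njit(cache=True)(_median_u8_py)
else:
    _median_u8_jit = None


def median_filter_u8(a: np.ndarray, window: int) -> np.ndarray:
    """Exact ``window`` x ``window`` median of a ``uint8`` image.

    Border pixels use edge replication.  Equivalent to
    ``scipy.ndimage.median_filter(a, size=window, mode="nearest")``.
    """
    if window % 2 == 0 or window < 3:
        raise ValueError(f"median window must be odd and >= 3, got {window}")
    a = np.ascontiguousarray(a, dtype=np.uint8)
    r = window // 2
    if _median_u8_jit is not None:
        return _median_u8_jit(a, r)
    return ndi.median_filter(a, size=window, mode="nearest")
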