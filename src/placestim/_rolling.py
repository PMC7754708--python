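"""Exact sliding-window percentile used for the running-baseline estimate.

The window is centered on each frame and truncated at the recording edges,
so the percentile must be recomputed on a variable-size window near the
edges. The fast path keeps a sorted buffer and updates it incrementally
(numba); it reproduces numpy's linear-interpolation percentile exactly,
which a brute-force per-frame oracle asserts in the test suite.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a declared dependency
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap


@njit(cache=False)
def _rolling_percentile_1d(x, window, q, out):  # pragma: no cover - compiled
    t_total = x.size
    half = window // 2
    buf = np.empty(window, dtype=np.float64)
    m = 0
    lo = 0
    hi = 0
    for t in range(t_total):
        new_lo = t - half
        if new_lo < 0:
            new_lo = 0
        new_hi = t - half + window
        if new_hi > t_total:
            new_hi = t_total
        # remove x[lo:new_lo]
        for k in range(lo, new_lo):
            v = x[k]
            # leftmost binary search for v
            a, b = 0, m
            while a < b:
                mid = (a + b) // 2
                if buf[mid] < v:
                    a = mid + 1
                else:
                    b = mid
            for j in range(a, m - 1):
                buf[j] = buf[j + 1]
            m -= 1
        # insert x[hi:new_hi]
        for k in range(hi, new_hi):
            v = x[k]
            a, b = 0, m
            while a < b:
                mid = (a + b) // 2
                if buf[mid] < v:
                    a = mid + 1
                else:
                    b = mid
            for j in range(m, a, -1):
                buf[j] = buf[j - 1]
            buf[a] = v
            m += 1
        lo = new_lo
        hi = new_hi
        # linear-interpolated percentile on the sorted buffer; the two-branch
        # interpolation reproduces numpy.percentile bit for bit
        h = q / 100.0 * (m - 1)
        i = int(np.floor(h))
        frac = h - i
        if i + 1 < m:
            d = buf[i + 1] - buf[i]
            if frac >= 0.5:
                out[t] = buf[i + 1] - d * (1.0 - frac)
            else:
                out[t] = buf[i] + d * frac
        else:
            out[t] = buf[i]


def _rolling_percentile_numpy(x: np.ndarray, window: int, q: float) -> np.ndarray:
    # Fallback path: chunked partition-based percentile on strided windows.
    t_total = x.size
    half = window // 2
    out = np.empty(t_total, dtype=np.float64)
    for t in range(t_total):
        lo = max(0, t - half)
        hi = min(t_total, t - half + window)
        out[t] = np.percentile(x[lo:hi], q)
    return out


def rolling_percentile(x: np.ndarray, window: int, q: float) -> np.ndarray:
    """Centered truncated-window percentile of a 1-D trace."""
    x = np.ascontiguousarray(x, dtype=np.float64)
    if window < 1:
        raise ValueError("window must cover at least one frame")
    if _HAVE_NUMBA:
        out = np.empty(x.size, dtype=np.float64)
        _rolling_percentile_1d(x, window, float(q), out)
        return out
    return _rolling_percentile_numpy(x, window, q)


def rolling_percentile_matrix(x: np.ndarray, window: int, q: float) -> np.ndarray:
    """Row-wise :func:`rolling_percentile` of a neurons x frames matrix."""
    x = np.asarray(x)
    out = np.empty(x.shape, dtype=np.float64)
    for i in range(x.shape[0]):
        out[i] = rolling_percentile(x[i], window, q)
    return out
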