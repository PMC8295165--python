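"""Single-pass numba helpers for hot elementwise/reduction patterns."""

from __future__ import annotations

import numba
import numpy as np


@numba.njit(cache=True)
def softmax_lastaxis_forward(x):  # x: [n, m] contiguous
    n, m = x.shape
    out = np.empty_like(x)
    for i in range(n):
        hi = x[i, 0]
        for j in range(1, m):
            if x[i, j] > hi:
                hi = x[i, j]
        total = 0.0
        for j in range(m):
            e = np.exp(x[i, j] - hi)
            out[i, j] = e
            total += e
        inv = 1.0 / total
        for j in range(m):
            out[i, j] *= inv
    return out


@numba.njit(cache=True)
def softmax_lastaxis_backward(y, g):  # both [n, m] contiguous
    n, m = y.shape
    out = np.empty_like(y)
    for i in range(n):
        dot = 0.0
        for j in range(m):
            dot += y[i, j] * g[i, j]
        for j in range(m):
            out[i, j] = y[i, j] * (g[i, j] - dot)
    return out
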