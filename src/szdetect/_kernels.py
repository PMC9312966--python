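"""Numba kernels for the quadratic-time signal descriptors.

These are the only operations in the feature engine without a vectorized
numpy formulation: the LZ76 phrase parse, dynamic time warping, the longest
common subsequence, and the recursive predominant-period estimator.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def lz76_phrase_count(bits: np.ndarray) -> int:
    """Number of LZ76 phrases in a binary sequence.

    Parsing from the left, each phrase is the longest prefix of the
    remaining sequence reproducible from the already-seen history (overlap
    allowed) plus one innovation symbol.  A trailing run that is entirely
    reproducible is not counted as a phrase, so a constant sequence has
    exactly one phrase.
    """
    n = bits.size
    c = 0
    p = 0
    while p < n:
        # longest match of bits[p:] against history starting before p
        best = 0
        for q in range(p):
            k = 0
            while p + k < n and bits[q + k] == bits[p + k]:
                k += 1
            if k > best:
                best = k
        if p + best >= n and best > 0:
            break  # trailing reproducible run
        c += 1
        p += best + 1
    return c


@njit(cache=True)
def dtw_cost(x: np.ndarray, y: np.ndarray) -> float:
    """Dynamic-time-warping cost, absolute-difference local cost, full window."""
    n, m = x.size, y.size
    prev = np.empty(m + 1)
    cur = np.empty(m + 1)
    prev[0] = 0.0
    for j in range(1, m + 1):
        prev[j] = np.inf
    for i in range(1, n + 1):
        cur[0] = np.inf
        xi = x[i - 1]
        for j in range(1, m + 1):
            d = abs(xi - y[j - 1])
            best = prev[j - 1]
            if prev[j] < best:
                best = prev[j]
            if cur[j - 1] < best:
                best = cur[j - 1]
            cur[j] = d + best
        prev, cur = cur, prev
    return prev[m]


@njit(cache=True)
def lcs_length(a: np.ndarray, b: np.ndarray) -> int:
    """Length of the longest common subsequence of two symbol arrays."""
    n, m = a.size, b.size
    prev = np.zeros(m + 1, dtype=np.int64)
    cur = np.zeros(m + 1, dtype=np.int64)
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            if ai == b[j - 1]:
                cur[j] = prev[j - 1] + 1
            elif prev[j] >= cur[j - 1]:
                cur[j] = prev[j]
            else:
                cur[j] = cur[j - 1]
        prev, cur = cur, prev
        for j in range(m + 1):
            cur[j] = 0
    return prev[m]


@njit(cache=True)
def nakamura_periods(x: np.ndarray, fs: float, alpha: float) -> tuple[float, float]:
    """Recursive predominant-period estimate tau_i = 2*pi*sqrt(X_i / D_i).

    X and D are exponentially smoothed squared displacement and squared
    velocity (first difference times fs).  Returns (tau at the window end,
    mean tau over the window); tau is 0 wherever D is 0.
    """
    n = x.size
    X = 0.0
    D = 0.0
    total = 0.0
    last = 0.0
    two_pi = 2.0 * np.pi
    for i in range(n):
        v = (x[i] - x[i - 1]) * fs if i > 0 else 0.0
        X = alpha * X + x[i] * x[i]
        D = alpha * D + v * v
        tau = two_pi * np.sqrt(X / D) if D > 0.0 else 0.0
        total += tau
        last = tau
    return last, total / n
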