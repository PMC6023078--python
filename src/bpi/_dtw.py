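"""Numba dynamic-programming kernels for dynamic time warping.

Local cost between scalar samples is the Euclidean distance |u_i - v_j|.
``band < 0`` disables the Sakoe-Chiba constraint.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_INF = np.inf


@njit(cache=True)
def dtw_cost(u: np.ndarray, v: np.ndarray, band: int) -> float:
    """DTW distance via a two-row DP sweep; O(a*b) time, O(b) memory."""
    a = u.shape[0]
    b = v.shape[0]
    prev = np.full(b + 1, _INF)
    curr = np.full(b + 1, _INF)
    prev[0] = 0.0
    for i in range(1, a + 1):
        if band >= 0:
            jlo = i - band if i - band > 1 else 1
            jhi = i + band if i + band < b else b
        else:
            jlo = 1
            jhi = b
        for j in range(jhi + 1):
            curr[j] = _INF
        for j in range(jlo, jhi + 1):
            c = abs(u[i - 1] - v[j - 1])
            m = prev[j]
            if prev[j - 1] < m:
                m = prev[j - 1]
            if curr[j - 1] < m:
                m = curr[j - 1]
            curr[j] = c + m
        tmp = prev
        prev = curr
        curr = tmp
    return prev[b]


@njit(cache=True)
def dtw_matrix(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Full (a+1) x (b+1) accumulated-cost matrix for path backtracking."""
    a = u.shape[0]
    b = v.shape[0]
    D = np.full((a + 1, b + 1), _INF)
    D[0, 0] = 0.0
    for i in range(1, a + 1):
        for j in range(1, b + 1):
            c = abs(u[i - 1] - v[j - 1])
            m = D[i - 1, j - 1]
            if D[i - 1, j] < m:
                m = D[i - 1, j]
            if D[i, j - 1] < m:
                m = D[i, j - 1]
            D[i, j] = c + m
    return D
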