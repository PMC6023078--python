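"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's dynamic-programming code paths:
DTW is checked by exhaustively enumerating every monotone, continuous,
boundary-anchored warp path and taking the cheapest.
"""

from __future__ import annotations

import numpy as np


def dtw_brute(u, v) -> float:
    """Minimum path cost by exhaustive enumeration (no memoisation)."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    a, b = len(u), len(v)
    best = [np.inf]

    def walk(i: int, j: int, cost: float) -> None:
        cost += abs(u[i] - v[j])
        if i == a - 1 and j == b - 1:
            if cost < best[0]:
                best[0] = cost
            return
        if i + 1 < a and j + 1 < b:
            walk(i + 1, j + 1, cost)
        if i + 1 < a:
            walk(i + 1, j, cost)
        if j + 1 < b:
            walk(i, j + 1, cost)

    walk(0, 0, 0.0)
    return best[0]


def confusion_brute(true_labels, pred_labels, class_ids) -> np.ndarray:
    """Counting with explicit loops, independent of sklearn."""
    k = len(class_ids)
    idx = {c: i for i, c in enumerate(class_ids)}
    out = np.zeros((k, k), dtype=int)
    for t, p in zip(true_labels, pred_labels):
        out[idx[t], idx[p]] += 1
    return out
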