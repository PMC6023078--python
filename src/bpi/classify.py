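"""Distance measures and 1-nearest-neighbour breath-pattern classification.

Two distances between breath envelopes are supported:

* **ED** — the plain Euclidean distance ``d(U,V) = sqrt(sum_i (u_i-v_i)^2)``
  between equal-length series (no warping; a length mismatch is an error,
  because the pipeline guarantees fixed 1000-sample envelopes and silent
  resampling would mask bugs upstream).
* **DTW** — dynamic time warping with local cost ``|u_i - v_j|`` and the
  recurrence ``D(i,j) = d(u_i,v_j) + min(D(i,j-1), D(i-1,j), D(i-1,j-1))``,
  which aligns temporally stretched or shifted repetitions of the same
  pattern.  An optional Sakoe-Chiba band bounds ``|i-j|`` for speed; no
  global constraint is applied by default.

Classification is 1-nearest-neighbour: the live envelope's distance to each
of the M templates forms an [M x 1] vector; the winning template's class
selects the output phrase.  Ties break toward the lowest template index.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple, Union

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_array, check_is_fitted

from . import _dtw
from .core import BreathEnvelope, EmptyLibraryError
from .library import TemplateLibrary, phrase_for_class

__all__ = [
    "WarpPath",
    "ClassificationResult",
    "euclidean_distance",
    "dtw_distance",
    "warp_path",
    "classify_1nn",
    "BreathPatternClassifier",
]

METRICS = ("ed", "dtw")


@dataclass
class WarpPath:
    """Alignment realising a DTW distance.

    ``pairs`` are 1-based ``(i, j)`` index pairs into series U (length a)
    and V (length b), satisfying the boundary condition (first pair (1,1),
    last (a,b)), continuity and monotonicity (each step increments i, j or
    both by exactly one), hence ``max(a,b) <= K <= a+b-1``.
    """

    pairs: List[Tuple[int, int]]

    @property
    def K(self) -> int:
        return len(self.pairs)


def _as_series(x: Union[np.ndarray, BreathEnvelope]) -> np.ndarray:
    if isinstance(x, BreathEnvelope):
        x = x.values
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError("series must be 1-D")
    return x


def euclidean_distance(u, v) -> float:
    """Euclidean distance between equal-length series."""
    u, v = _as_series(u), _as_series(v)
    if u.size != v.size:
        raise ValueError(
            f"ED requires equal lengths, got {u.size} and {v.size} "
            "(use DTW for unequal-length series)"
        )
    return float(np.sqrt(np.sum((u - v) ** 2)))


def _check_band(a: int, b: int, band_width: Optional[int]) -> int:
    if band_width is None:
        return -1
    band_width = int(band_width)
    if band_width < abs(a - b):
        raise ValueError(
            f"band_width={band_width} infeasible for lengths {a} and {b} "
            f"(need >= {abs(a - b)})"
        )
    return band_width


def dtw_distance(u, v, band_width: Optional[int] = None) -> float:
    """DTW distance with |.| local cost; symmetric, zero iff an exact
    monotone alignment of identical values exists."""
    u, v = _as_series(u), _as_series(v)
    if u.size == 0 or v.size == 0:
        raise ValueError("DTW requires non-empty series")
    band = _check_band(u.size, v.size, band_width)
    return float(_dtw.dtw_cost(u, v, band))


def warp_path(u, v) -> WarpPath:
    """Backtrack the optimal warp path (ties prefer the diagonal step)."""
    u, v = _as_series(u), _as_series(v)
    if u.size == 0 or v.size == 0:
        raise ValueError("DTW requires non-empty series")
    D = _dtw.dtw_matrix(u, v)
    i, j = u.size, v.size
    pairs = [(i, j)]
    while (i, j) != (1, 1):
        candidates = (
            (D[i - 1, j - 1], (i - 1, j - 1)),  # diagonal preferred on ties
            (D[i - 1, j], (i - 1, j)),
            (D[i, j - 1], (i, j - 1)),
        )
        best = min(candidates, key=lambda c: c[0])
        i, j = best[1]
        pairs.append((i, j))
    pairs.reverse()
    return WarpPath(pairs)


@dataclass
class ClassificationResult:
    """Outcome of classifying one live envelope against a library."""

    predicted_class: int
    distances: np.ndarray  # (M,), one per template
    nearest_template_index: int
    metric_name: str
    phrase: str


def classify_1nn(
    live: Union[np.ndarray, BreathEnvelope],
    lib: TemplateLibrary,
    metric: str = "dtw",
    band_width: Optional[int] = None,
) -> ClassificationResult:
    """1-NN classification of a live envelope against the template library."""
    metric = metric.lower()
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}, got {metric!r}")
    if len(lib.templates) == 0:
        raise EmptyLibraryError("template library holds no templates")
    x = _as_series(live)
    dists = np.empty(len(lib.templates))
    for k, tpl in enumerate(lib.templates):
        if metric == "ed":
            dists[k] = euclidean_distance(x, tpl.values)
        else:
            dists[k] = dtw_distance(x, tpl.values, band_width)
    nearest = int(np.argmin(dists))  # argmin takes the lowest index on ties
    cid = int(lib.templates[nearest].class_label)
    return ClassificationResult(
        predicted_class=cid,
        distances=dists,
        nearest_template_index=nearest,
        metric_name=metric.upper(),
        phrase=phrase_for_class(lib, cid),
    )


class BreathPatternClassifier(ClassifierMixin, BaseEstimator):
    """1-nearest-neighbour template classifier over breath envelopes.

    Parameters
    ----------
    metric : {"dtw", "ed"}
        Distance between the query envelope and each stored template.
    band_width : int, optional
        Sakoe-Chiba band half-width in samples for DTW; ``None`` leaves the
        warp unconstrained.

    Attributes
    ----------
    templates_ : ndarray of shape (M, env_len)
        The training envelopes, stored row-wise (the "M by samples" layout).
    template_labels_ : ndarray of shape (M,)
        Class label of each template row.
    classes_ : ndarray
        Sorted unique class labels.
    """

    def __init__(self, metric: str = "dtw", band_width: Optional[int] = None):
        self.metric = metric
        self.band_width = band_width

    def fit(self, X, y):
        if self.metric.lower() not in METRICS:
            raise ValueError(f"metric must be one of {METRICS}, got {self.metric!r}")
        X = check_array(X, dtype=np.float64)
        y = np.asarray(y)
        if y.shape[0] != X.shape[0]:
            raise ValueError("X and y length mismatch")
        if X.shape[0] == 0:
            raise EmptyLibraryError("cannot fit on an empty template set")
        self.templates_ = X
        self.template_labels_ = y
        self.classes_ = np.unique(y)
        self.n_features_in_ = X.shape[1]
        return self

    def distance_matrix(self, X) -> np.ndarray:
        """Pairwise distances, shape (n_queries, M): one [M x 1] distance
        vector per query envelope."""
        check_is_fitted(self, "templates_")
        X = check_array(X, dtype=np.float64)
        metric = self.metric.lower()
        if metric == "ed" and X.shape[1] != self.templates_.shape[1]:
            raise ValueError(
                f"ED requires query length {self.templates_.shape[1]}, got {X.shape[1]}"
            )
        out = np.empty((X.shape[0], self.templates_.shape[0]))
        for i, row in enumerate(X):
            for k, tpl in enumerate(self.templates_):
                if metric == "ed":
                    out[i, k] = euclidean_distance(row, tpl)
                else:
                    out[i, k] = dtw_distance(row, tpl, self.band_width)
        return out

    def predict(self, X):
        d = self.distance_matrix(X)
        return self.template_labels_[np.argmin(d, axis=1)]
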