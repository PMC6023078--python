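"""Distances and 1-NN classification: closed-form checks, brute-force
oracle equivalence, warp-path invariants, and classifier behaviour."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bpi.classify import (
    BreathPatternClassifier,
    classify_1nn,
    dtw_distance,
    euclidean_distance,
    warp_path,
)
from bpi.core import BreathEnvelope, EmptyLibraryError
from bpi.library import DEFAULT_VOCABULARY, TemplateLibrary, build_library
from oracles import dtw_brute

series = st.lists(
    st.floats(min_value=-5, max_value=5, allow_nan=False), min_size=1, max_size=8
).map(np.array)


class TestEuclidean:
    def test_identity(self, rng):
        x = rng.standard_normal(20)
        assert euclidean_distance(x, x) == 0.0

    def test_closed_forms(self):
        assert euclidean_distance([0, 0], [1, 1]) == pytest.approx(np.sqrt(2))
        assert euclidean_distance([1, 2, 3], [4, 5, 6]) == pytest.approx(np.sqrt(27))

    def test_length_mismatch_is_error(self):
        with pytest.raises(ValueError):
            euclidean_distance([1, 2], [1, 2, 3])

    @given(series, series)
    @settings(derandomize=True, max_examples=50)
    def test_symmetry_nonnegativity(self, u, v):
        if len(u) != len(v):
            return
        d = euclidean_distance(u, v)
        assert d >= 0
        assert d == pytest.approx(euclidean_distance(v, u))


class TestDtw:
    def test_identity_and_closed_forms(self, rng):
        x = rng.standard_normal(30)
        assert dtw_distance(x, x) == 0.0
        assert dtw_distance([1, 2, 3], [1, 1, 2, 2, 3, 3]) == 0.0
        assert dtw_distance([0, 0], [1, 1]) == 2.0

    def test_duplicate_stretch_invariance(self, rng):
        """Duplicating each sample is a free warp for DTW but costs ED."""
        x = rng.standard_normal(15)
        x2 = np.repeat(x, 2)
        assert dtw_distance(x, x2) == 0.0
        # ED on a length-matched linear resampling is strictly positive
        x_resamp = np.interp(np.linspace(0, len(x) - 1, len(x2)), np.arange(len(x)), x)
        assert euclidean_distance(x_resamp, x2) > 0

    def test_oracle_equivalence_small(self, rng):
        for _ in range(30):
            u = rng.standard_normal(int(rng.integers(1, 7)))
            v = rng.standard_normal(int(rng.integers(1, 7)))
            assert dtw_distance(u, v) == pytest.approx(dtw_brute(u, v), abs=1e-9)

    def test_dtw_leq_locked_diagonal(self, rng):
        """Warping can only lower the |.|-cost relative to the diagonal."""
        for _ in range(20):
            u = rng.standard_normal(12)
            v = rng.standard_normal(12)
            assert dtw_distance(u, v) <= np.sum(np.abs(u - v)) + 1e-12

    def test_band_constraint(self, rng):
        u = rng.standard_normal(20)
        v = rng.standard_normal(24)
        with pytest.raises(ValueError):
            dtw_distance(u, v, band_width=2)  # infeasible: |a-b|=4
        full = dtw_distance(u, v)
        banded = dtw_distance(u, v, band_width=24)
        assert banded == pytest.approx(full)  # wide band = unconstrained
        assert dtw_distance(u, v, band_width=5) >= full - 1e-12

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            dtw_distance([], [1.0])

    @given(series, series)
    @settings(derandomize=True, max_examples=60)
    def test_symmetry_and_oracle(self, u, v):
        d = dtw_distance(u, v)
        assert d >= 0
        assert d == pytest.approx(dtw_distance(v, u), abs=1e-9)
        assert d == pytest.approx(dtw_brute(u, v), abs=1e-9)


def _check_path_invariants(path, a, b):
    assert path.pairs[0] == (1, 1)
    assert path.pairs[-1] == (a, b)
    assert max(a, b) <= path.K <= a + b - 1
    for (i1, j1), (i2, j2) in zip(path.pairs, path.pairs[1:]):
        di, dj = i2 - i1, j2 - j1
        assert (di, dj) in ((1, 0), (0, 1), (1, 1))


class TestWarpPath:
    def test_identity_path_is_diagonal(self, rng):
        x = rng.standard_normal(6)
        path = warp_path(x, x)
        assert path.pairs == [(i, i) for i in range(1, 7)]

    def test_duplicate_stretch_path(self):
        path = warp_path([1, 2, 3], [1, 1, 2, 2, 3, 3])
        assert path.K == 6
        assert sorted({j for _, j in path.pairs}) == [1, 2, 3, 4, 5, 6]
        _check_path_invariants(path, 3, 6)

    @given(series, series)
    @settings(derandomize=True, max_examples=60)
    def test_invariants_and_cost_consistency(self, u, v):
        path = warp_path(u, v)
        _check_path_invariants(path, len(u), len(v))
        cost = sum(abs(u[i - 1] - v[j - 1]) for i, j in path.pairs)
        assert cost == pytest.approx(dtw_distance(u, v), rel=1e-9, abs=1e-12)


class TestClassify1NN:
    def test_exact_template_wins(self, small_library):
        tpl_idx = 7
        live = small_library.templates[tpl_idx]
        res = classify_1nn(live, small_library, metric="ed")
        assert res.distances[tpl_idx] == 0.0
        assert res.nearest_template_index == tpl_idx
        assert res.predicted_class == small_library.templates[tpl_idx].class_label
        assert res.phrase == dict(
            (v.class_id, v.phrase) for v in small_library.vocabulary
        )[res.predicted_class]
        assert len(res.distances) == small_library.M

    def test_single_class_library_always_answers_it(self, rng):
        envs = {1: [BreathEnvelope(np.abs(rng.standard_normal(50)), 100.0)]}
        lib = build_library(envs, DEFAULT_VOCABULARY)
        res = classify_1nn(np.abs(rng.standard_normal(50)), lib, metric="dtw")
        assert res.predicted_class == 1

    @pytest.mark.parametrize("metric", ["ed", "dtw"])
    def test_matches_brute_force_argmin(self, small_library, metric, rng):
        """Predictions equal an independently recomputed argmin."""
        for _ in range(5):
            live = np.abs(rng.standard_normal(small_library.env_len))
            res = classify_1nn(live, small_library, metric=metric)
            dists = []
            for tpl in small_library.templates:
                if metric == "ed":
                    dists.append(float(np.sqrt(np.sum((live - tpl.values) ** 2))))
                else:
                    dists.append(dtw_brute_big(live, tpl.values))
            k = int(np.argmin(dists))
            assert res.nearest_template_index == k
            assert res.predicted_class == small_library.templates[k].class_label
            np.testing.assert_allclose(res.distances, dists, rtol=1e-9)

    def test_empty_library_rejected(self):
        lib = TemplateLibrary([], DEFAULT_VOCABULARY, 100.0, 10)
        with pytest.raises(EmptyLibraryError):
            classify_1nn(np.zeros(10), lib)


def dtw_brute_big(u, v):
    """Reference DTW for longer series: plain-python DP over the full
    table (no shared code with the numba kernels)."""
    a, b = len(u), len(v)
    D = np.full((a + 1, b + 1), np.inf)
    D[0, 0] = 0.0
    for i in range(1, a + 1):
        for j in range(1, b + 1):
            D[i, j] = abs(u[i - 1] - v[j - 1]) + min(
                D[i - 1, j - 1], D[i - 1, j], D[i, j - 1]
            )
    return float(D[a, b])


class TestBreathPatternClassifier:
    def test_fit_predict_round_trip(self, small_library):
        X = small_library.as_matrix()
        y = small_library.labels()
        clf = BreathPatternClassifier(metric="ed").fit(X, y)
        assert np.array_equal(clf.predict(X), y)
        assert clf.score(X, y) == 1.0

    def test_distance_matrix_shape(self, small_library):
        X = small_library.as_matrix()
        clf = BreathPatternClassifier(metric="dtw").fit(X, small_library.labels())
        d = clf.distance_matrix(X[:3])
        assert d.shape == (3, small_library.M)
        assert np.allclose(np.diag(d[:3, :3]), 0.0)

    def test_determinism_across_runs(self, small_library, rng):
        X = small_library.as_matrix()
        y = small_library.labels()
        q = np.abs(rng.standard_normal((4, small_library.env_len)))
        p1 = BreathPatternClassifier(metric="dtw").fit(X, y).predict(q)
        p2 = BreathPatternClassifier(metric="dtw").fit(X, y).predict(q)
        assert np.array_equal(p1, p2)

    def test_ed_length_mismatch_rejected(self, small_library):
        clf = BreathPatternClassifier(metric="ed").fit(
            small_library.as_matrix(), small_library.labels()
        )
        with pytest.raises(ValueError):
            clf.distance_matrix(np.zeros((1, small_library.env_len + 5)))

    def test_sklearn_clone_compatible(self, small_library):
        from sklearn.base import clone

        clf = BreathPatternClassifier(metric="ed", band_width=3)
        c2 = clone(clf)
        assert c2.get_params() == clf.get_params()
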