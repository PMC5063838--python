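"""Circumcircle construction, circumference sampling, and fitness."""

import numpy as np
import pytest

from pgsawbc.circle import (
    CandidateCircle,
    CircleParams,
    DegenerateTripleError,
    EdgeSet,
    EmptySampleError,
    candidate_from_indices,
    circumcircle,
    fitness,
    sample_circumference,
)
from pgsawbc.preprocess import EdgePixelVector

from conftest import brute_force_ring


def bisector_circumcenter(p1, p2, p3):
    """Independent oracle: intersect the perpendicular bisectors of
    (p1,p2) and (p1,p3) by solving the 2x2 linear system."""
    p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p1, p2, p3))
    a = np.array([p2 - p1, p3 - p1])
    b = np.array([
        (p2 @ p2 - p1 @ p1) / 2.0,
        (p3 @ p3 - p1 @ p1) / 2.0,
    ])
    center = np.linalg.solve(a, b)
    return center, float(np.linalg.norm(center - p1))


class TestCircumcircle:
    def test_right_triangle(self):
        c = circumcircle((0, 0), (2, 0), (0, 2))
        assert c.x0 == pytest.approx(1.0)
        assert c.y0 == pytest.approx(1.0)
        assert c.r == pytest.approx(np.sqrt(2.0))

    def test_collinear_rejected(self):
        with pytest.raises(DegenerateTripleError):
            circumcircle((0, 0), (1, 1), (2, 2))

    def test_matches_bisector_oracle_on_random_triples(self, rng):
        checked = 0
        while checked < 300:
            pts = rng.integers(0, 400, size=(3, 2))
            u, v = pts[1] - pts[0], pts[2] - pts[0]
            if u[0] * v[1] - u[1] * v[0] == 0:
                continue
            c = circumcircle(*pts)
            (ox, oy), orad = bisector_circumcenter(*pts)
            scale = max(1.0, abs(ox), abs(oy), orad)
            assert abs(c.x0 - ox) <= 1e-9 * scale
            assert abs(c.y0 - oy) <= 1e-9 * scale
            assert abs(c.r - orad) <= 1e-9 * scale
            # all three anchors equidistant
            d = [np.hypot(c.x0 - x, c.y0 - y) for x, y in pts]
            assert max(d) - min(d) <= 1e-9 * scale
            checked += 1


def _ring_vector(x0, y0, r, shape=(200, 200)):
    ring = brute_force_ring(shape, x0, y0, r)
    return EdgePixelVector.from_bool_image(ring)


class TestCandidateFromIndices:
    def test_recovers_rasterized_circle(self):
        P = _ring_vector(100, 100, 30)
        n = len(P)
        # three well-spread indices
        cand = candidate_from_indices(P, 0, n // 3, 2 * n // 3,
                                      r_min=5, r_max=100)
        assert cand is not None
        assert abs(cand.params.x0 - 100) <= 1
        assert abs(cand.params.y0 - 100) <= 1
        assert abs(cand.params.r - 30) <= 1

    def test_radius_bound_rejection(self):
        P = _ring_vector(100, 100, 30)
        n = len(P)
        cand = candidate_from_indices(P, 0, n // 3, 2 * n // 3,
                                      r_min=5, r_max=20)
        assert cand is None

    def test_near_collinear_adjacent_pixels(self):
        pts = np.array([[10, 10], [20, 10], [30, 10], [30, 11]])
        P = EdgePixelVector(points=pts, shape=(50, 50))
        with pytest.raises(DegenerateTripleError):
            candidate_from_indices(P, 0, 1, 2, r_min=1, r_max=1000)
        # near-collinear: valid circle but huge radius -> rejected by bound
        assert candidate_from_indices(P, 0, 1, 3, r_min=1, r_max=10) is None

    def test_duplicate_indices_rejected(self):
        P = _ring_vector(100, 100, 30)
        with pytest.raises(ValueError):
            candidate_from_indices(P, 1, 1, 2, r_min=5, r_max=100)

    def test_key_is_order_free(self):
        P = _ring_vector(100, 100, 30)
        n = len(P)
        a = candidate_from_indices(P, 0, n // 3, 2 * n // 3, r_min=5, r_max=100)
        b = candidate_from_indices(P, 2 * n // 3, 0, n // 3, r_min=5, r_max=100)
        assert a.key == b.key


class TestSampleCircumference:
    def test_unit_radius_eight_connected_ring(self):
        sample = sample_circumference(CircleParams(5, 5, 1), (20, 20))
        expected = {(6, 5), (4, 5), (5, 6), (5, 4),
                    (6, 6), (6, 4), (4, 6), (4, 4)}
        assert {tuple(p) for p in sample.points} == expected
        assert sample.n == 8

    def test_matches_brute_force_band(self, rng):
        for _ in range(10):
            x0 = float(rng.uniform(20, 80))
            y0 = float(rng.uniform(20, 80))
            r = float(rng.uniform(5, 18))
            sample = sample_circumference(CircleParams(x0, y0, r), (100, 100))
            oracle = brute_force_ring((100, 100), x0, y0, r, band=0.5)
            got = np.zeros((100, 100), dtype=bool)
            got[sample.points[:, 1], sample.points[:, 0]] = True
            assert np.array_equal(got, oracle)

    def test_corner_circle_keeps_quarter(self):
        full = sample_circumference(CircleParams(50, 50, 20), (200, 200))
        corner = sample_circumference(CircleParams(0, 0, 20), (200, 200))
        assert abs(corner.n - full.n / 4) <= 2
        assert np.all(corner.points >= 0)

    def test_band_property(self, rng):
        p = CircleParams(33.3, 41.7, 12.9)
        sample = sample_circumference(p, (100, 100))
        d = np.hypot(sample.points[:, 0] - p.x0, sample.points[:, 1] - p.y0)
        assert np.all(np.abs(d - p.r) <= 0.75)

    def test_out_of_bounds_circle_errors(self):
        with pytest.raises(EmptySampleError):
            sample_circumference(CircleParams(1000, 1000, 5), (100, 100))


def _candidate_with_params(params):
    return CandidateCircle(e1=0, e2=1, e3=2, params=params)


class TestFitness:
    def test_perfect_candidate_on_empty_mask(self):
        shape = (120, 120)
        params = CircleParams(60, 60, 25)
        sample = sample_circumference(params, shape)
        P = EdgePixelVector(points=sample.points, shape=shape)
        edges = EdgeSet(P, tolerance=0)
        mask = np.zeros(shape, dtype=np.uint8)
        bd = fitness(_candidate_with_params(params), edges, mask)
        assert bd.coverage == pytest.approx(1.0)
        assert bd.wp == 0
        assert bd.value == pytest.approx(0.0)

    def test_blank_edge_map_blank_mask(self):
        shape = (120, 120)
        P = EdgePixelVector(points=np.empty((0, 2), dtype=int), shape=shape)
        edges = EdgeSet(P, tolerance=0)
        mask = np.zeros(shape, dtype=np.uint8)
        bd = fitness(_candidate_with_params(CircleParams(60, 60, 25)), edges, mask)
        assert bd.coverage == 0.0
        assert bd.value == pytest.approx(1.0)

    def test_full_foreground_interior_engages_bp_guard(self):
        shape = (120, 120)
        params = CircleParams(60, 60, 20)
        P = EdgePixelVector(points=np.empty((0, 2), dtype=int), shape=shape)
        edges = EdgeSet(P, tolerance=0)
        # mask: foreground disc strictly larger than the candidate
        gy, gx = np.mgrid[0:120, 0:120]
        mask = (np.hypot(gx - 60, gy - 60) < 30).astype(np.uint8)
        bd = fitness(_candidate_with_params(params), edges, mask)
        # brute-force interior count
        wp_oracle = int(sum(
            1 for y in range(120) for x in range(120)
            if np.hypot(x - 60, y - 60) < 20 and mask[y, x]))
        assert bd.wp == wp_oracle
        assert bd.bp == 0
        assert bd.value == pytest.approx(1.0 - bd.coverage - wp_oracle)

    def test_monotone_in_edge_support_and_interior(self):
        shape = (120, 120)
        params = CircleParams(60, 60, 25)
        sample = sample_circumference(params, shape)
        mask = np.zeros(shape, dtype=np.uint8)
        # growing edge support never increases the fitness value
        prev = None
        for n_keep in (0, len(sample.points) // 2, len(sample.points)):
            P = EdgePixelVector(points=sample.points[:n_keep], shape=shape)
            bd = fitness(_candidate_with_params(params),
                         EdgeSet(P, tolerance=0), mask)
            if prev is not None:
                assert bd.value <= prev + 1e-12
            prev = bd.value
        # adding a foreground pixel strictly inside never increases it
        P = EdgePixelVector(points=sample.points, shape=shape)
        edges = EdgeSet(P, tolerance=0)
        base = fitness(_candidate_with_params(params), edges, mask).value
        mask2 = mask.copy()
        mask2[60, 60] = 1
        richer = fitness(_candidate_with_params(params), edges, mask2).value
        assert richer <= base + 1e-12

    def test_true_circle_beats_displaced_candidates(self):
        shape = (200, 200)
        params = CircleParams(100, 100, 30)
        ring = brute_force_ring(shape, 100, 100, 30)
        P = EdgePixelVector.from_bool_image(ring)
        edges = EdgeSet(P, tolerance=0)
        mask = np.zeros(shape, dtype=np.uint8)
        best = fitness(_candidate_with_params(params), edges, mask).value
        for dx, dy, dr in [(3, 0, 0), (0, 3, 0), (0, 0, 3), (0, 0, -3),
                           (3, 3, 0), (-3, 0, 3)]:
            moved = CircleParams(100 + dx, 100 + dy, 30 + dr)
            val = fitness(_candidate_with_params(moved), edges, mask).value
            assert best <= val

    def test_chebyshev_tolerance_widens_membership(self):
        shape = (120, 120)
        params = CircleParams(60, 60, 25)
        sample = sample_circumference(params, shape)
        # shift the edge map one pixel: exact membership collapses,
        # Chebyshev-1 membership stays near-perfect
        shifted = sample.points + np.array([1, 0])
        shifted = shifted[(shifted[:, 0] < 120)]
        P = EdgePixelVector(points=shifted, shape=shape)
        mask = np.zeros(shape, dtype=np.uint8)
        exact = fitness(_candidate_with_params(params),
                        EdgeSet(P, tolerance=0), mask)
        tol1 = fitness(_candidate_with_params(params),
                       EdgeSet(P, tolerance=1), mask)
        assert tol1.coverage >= exact.coverage
        assert tol1.coverage >= 0.95

    def test_mismatched_mask_dims_rejected(self):
        P = EdgePixelVector(points=np.empty((0, 2), dtype=int), shape=(50, 50))
        with pytest.raises(ValueError):
            fitness(_candidate_with_params(CircleParams(10, 10, 5)),
                    EdgeSet(P), np.zeros((40, 40), dtype=np.uint8))
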