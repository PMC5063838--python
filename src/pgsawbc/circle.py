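"""Candidate circles: construction from edge-index triples and fitness.

A candidate C is three distinct indices (e1, e2, e3) into the edge-pixel
vector P; its parameters [x0, y0, r] are the circumcircle of the three
indexed points. The fitness

    f(C) = 1 - coverage - W_p / max(B_p, 1)

combines how much of the candidate's rasterised circumference coincides
with edge pixels (coverage = sum E(j_i) / N) with the segmentation content
of its strict interior: W_p foreground ("white") pixels reward candidates
enclosing a cell body, B_p background pixels penalise spilling over. Lower
fitness is better; 1.0 is the score of a candidate with no support at all.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .preprocess import EdgePixelVector

__all__ = [
    "CircleParams",
    "CandidateCircle",
    "CircumferenceSample",
    "FitnessBreakdown",
    "EdgeSet",
    "DegenerateTripleError",
    "EmptySampleError",
    "circumcircle",
    "candidate_from_indices",
    "sample_circumference",
    "fitness",
]


class DegenerateTripleError(ValueError):
    """The three points are (near-)collinear: no finite circumcircle."""


class EmptySampleError(ValueError):
    """The circle's rasterised circumference has no in-bounds pixel."""


@dataclass(frozen=True)
class CircleParams:
    """Circle centre (x0, y0) and radius r, in pixels, real-valued."""

    x0: float
    y0: float
    r: float

    def __post_init__(self):
        if not (np.isfinite(self.x0) and np.isfinite(self.y0) and np.isfinite(self.r)):
            raise ValueError("circle parameters must be finite")
        if self.r <= 0:
            raise ValueError("radius must be positive")


@dataclass
class CandidateCircle:
    """An edge-index triple with its derived circle and (optional) fitness."""

    e1: int
    e2: int
    e3: int
    params: CircleParams
    fitness: float | None = None
    breakdown: "FitnessBreakdown | None" = None

    @property
    def key(self) -> tuple[int, int, int]:
        """Order-free identity of the triple (duplicates collapse on this)."""
        return tuple(sorted((self.e1, self.e2, self.e3)))


@dataclass(frozen=True)
class CircumferenceSample:
    """Integer pixels J = {j_1 ... j_N} approximating a circumference."""

    points: np.ndarray        # (N, 2) int array of (x, y)
    n: int

    def __post_init__(self):
        object.__setattr__(self, "points",
                           np.asarray(self.points, dtype=np.int64).reshape(-1, 2))
        if self.n != len(self.points):
            raise ValueError("count does not match point list")


@dataclass(frozen=True)
class FitnessBreakdown:
    """The three terms of f(C) plus the final value."""

    coverage: float
    wp: int
    bp: int
    n: int
    value: float


def circumcircle(p1, p2, p3, tol: float = 1e-9) -> CircleParams:
    """Unique circle through three non-collinear points.

    Centre from the 2x2 determinant formulas over the common denominator
    4*((xj-xi)(yk-yi) - (xk-xi)(yj-yi)); radius is the distance from the
    centre to the anchor points (all three agree to 1e-6 by construction).
    Collinear triples (|denominator| < tol * scale) raise
    :class:`DegenerateTripleError` — the caller should resample.
    """
    (xi, yi), (xj, yj), (xk, yk) = (map(float, p) for p in (p1, p2, p3))
    denom = 4.0 * ((xj - xi) * (yk - yi) - (xk - xi) * (yj - yi))
    scale = max(1.0, max(abs(v) for v in (xi, yi, xj, yj, xk, yk)) ** 2)
    if abs(denom) < tol * scale:
        raise DegenerateTripleError(f"collinear points: {p1}, {p2}, {p3}")
    aj = xj * xj + yj * yj - (xi * xi + yi * yi)
    ak = xk * xk + yk * yk - (xi * xi + yi * yi)
    det_a = aj * 2.0 * (yk - yi) - ak * 2.0 * (yj - yi)
    det_b = 2.0 * (xj - xi) * ak - 2.0 * (xk - xi) * aj
    x0 = det_a / denom
    y0 = det_b / denom
    r = float(np.hypot(x0 - xi, y0 - yi))
    return CircleParams(x0=x0, y0=y0, r=r)


def candidate_from_indices(
    P: EdgePixelVector,
    e1: int,
    e2: int,
    e3: int,
    r_min: float,
    r_max: float,
) -> CandidateCircle | None:
    """Build a candidate from three edge-vector indices.

    Returns ``None`` (a rejection, not an error) when the circumcircle's
    centre falls outside the image or its radius is outside
    [``r_min``, ``r_max``]. Degenerate (collinear) triples raise
    :class:`DegenerateTripleError` so the caller can resample.
    """
    if len({e1, e2, e3}) != 3:
        raise ValueError("indices must be distinct")
    n = len(P)
    for e in (e1, e2, e3):
        if not 0 <= e < n:
            raise IndexError(f"index {e} outside [0, {n})")
    params = circumcircle(P.points[e1], P.points[e2], P.points[e3])
    h, w = P.shape
    if not (0 <= params.x0 < w and 0 <= params.y0 < h):
        return None
    if not (r_min <= params.r <= r_max):
        return None
    return CandidateCircle(e1=int(e1), e2=int(e2), e3=int(e3), params=params)


def sample_circumference(
    params: CircleParams, bounds: tuple[int, int]
) -> CircumferenceSample:
    """Rasterise a circle's circumference onto the pixel grid.

    Midpoint rule: the sample is every in-bounds integer pixel whose
    Euclidean distance to the (real-valued) centre is within 0.5 px of r.
    Pixels outside the image are dropped; an entirely out-of-bounds circle
    raises :class:`EmptySampleError`.
    """
    h, w = bounds
    x_lo = max(0, int(np.floor(params.x0 - params.r - 1)))
    x_hi = min(w - 1, int(np.ceil(params.x0 + params.r + 1)))
    y_lo = max(0, int(np.floor(params.y0 - params.r - 1)))
    y_hi = min(h - 1, int(np.ceil(params.y0 + params.r + 1)))
    if x_lo > x_hi or y_lo > y_hi:
        raise EmptySampleError("circle entirely outside image bounds")
    xs = np.arange(x_lo, x_hi + 1)
    ys = np.arange(y_lo, y_hi + 1)
    gx, gy = np.meshgrid(xs, ys)
    dist = np.hypot(gx - params.x0, gy - params.y0)
    band = np.abs(dist - params.r) <= 0.5
    if not band.any():
        raise EmptySampleError("no in-bounds circumference pixel")
    pts = np.column_stack([gx[band], gy[band]])
    return CircumferenceSample(points=pts, n=len(pts))


class EdgeSet:
    """Membership structure over an edge-pixel vector.

    With ``tolerance=0`` membership is exact pixel identity; a positive
    tolerance t accepts any pixel within Chebyshev distance t of an edge
    pixel (useful for noisy maps and for rasterisation off-by-half-pixel
    effects between a candidate's circumference band and a one-pixel
    edge ring).
    """

    def __init__(self, P: EdgePixelVector, tolerance: int = 0):
        if tolerance < 0:
            raise ValueError("tolerance must be >= 0")
        self.P = P
        self.tolerance = int(tolerance)
        self._exact = P.to_bool_image()
        if tolerance > 0 and len(P):
            size = 2 * tolerance + 1
            self._member = ndimage.binary_dilation(
                self._exact, structure=np.ones((size, size), dtype=bool))
        else:
            self._member = self._exact

    def contains(self, xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
        return self._member[ys, xs]


def fitness(
    candidate: CandidateCircle,
    edges: EdgeSet,
    mask: np.ndarray,
) -> FitnessBreakdown:
    """Score a candidate with f(C) = 1 - coverage - W_p / max(B_p, 1).

    Coverage is the fraction of the candidate's circumference sample that
    are edge pixels (E(j_i) = 1 on membership in ``edges``); W_p and B_p
    count mask-foreground and mask-background pixels strictly inside the
    circle (distance < r, circumference pixels excluded). The B_p >= 1
    guard keeps the value finite when the interior is pure foreground.
    The breakdown is stored on the candidate as a side effect.
    """
    mask = np.asarray(mask)
    if mask.shape != edges.P.shape:
        raise ValueError("mask dimensions must match the edge map")
    sample = sample_circumference(candidate.params, mask.shape)
    hits = edges.contains(sample.points[:, 0], sample.points[:, 1])
    coverage = float(hits.mean())

    p = candidate.params
    h, w = mask.shape
    x_lo = max(0, int(np.floor(p.x0 - p.r)))
    x_hi = min(w - 1, int(np.ceil(p.x0 + p.r)))
    y_lo = max(0, int(np.floor(p.y0 - p.r)))
    y_hi = min(h - 1, int(np.ceil(p.y0 + p.r)))
    wp = bp = 0
    if x_lo <= x_hi and y_lo <= y_hi:
        xs = np.arange(x_lo, x_hi + 1)
        ys = np.arange(y_lo, y_hi + 1)
        gx, gy = np.meshgrid(xs, ys)
        inside = np.hypot(gx - p.x0, gy - p.y0) < p.r
        vals = mask[y_lo:y_hi + 1, x_lo:x_hi + 1][inside]
        wp = int(np.count_nonzero(vals))
        bp = int(vals.size - wp)
    value = 1.0 - coverage - wp / max(bp, 1)
    breakdown = FitnessBreakdown(coverage=coverage, wp=wp, bp=bp,
                                 n=sample.n, value=value)
    candidate.fitness = value
    candidate.breakdown = breakdown
    return breakdown
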