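"""Leukocyte detection model: preprocess, optimise, extract circles.

`CircleDetector` is built from an image (statsmodels-style): construction
runs the deterministic preprocessing (segmentation, edge map), `fit(seed)`
runs the stochastic search and returns a `DetectionResults` carrying the
detections, their scores, provenance and presentation helpers.

Multi-circle extraction loops the plant-growth optimiser: after each run
the best candidate is accepted if its circumference coverage reaches the
threshold alpha, its edge support (all pixels within delta of the circle)
is erased from P, and the search restarts fresh on the remainder. The
loop stops at the first sub-threshold best, when fewer edge pixels remain
than `min_edge_points`, or at `max_circles`. Centres and radii stay
real-valued (sub-pixel); only circumference sampling rasterises.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import pgsa
from .circle import (
    CandidateCircle,
    CircleParams,
    DegenerateTripleError,
    EdgeSet,
    EmptySampleError,
    candidate_from_indices,
    fitness,
    sample_circumference,
)
from .config import RunConfig
from .preprocess import (
    EdgePixelVector,
    canny_edges,
    morphological_edge_map,
    read_image,
    segment_histogram_threshold,
    to_grayscale,
)

__all__ = [
    "Detection",
    "DetectionResults",
    "CircleDetector",
    "detect",
    "erase_support",
    "render_overlay",
]


@dataclass(frozen=True)
class Detection:
    """One accepted circle, in discovery order (order >= 1)."""

    params: CircleParams
    fitness: float
    coverage: float
    order: int


def erase_support(P: EdgePixelVector, params: CircleParams,
                  delta: float) -> EdgePixelVector:
    """Remove from P every point within ``delta`` px of the circle's
    circumference (|distance-to-centre - r| <= delta); survivor order is
    preserved."""
    if delta <= 0:
        raise ValueError("delta must be > 0")
    if len(P) == 0:
        return P
    d = np.hypot(P.points[:, 0] - params.x0, P.points[:, 1] - params.y0)
    keep = np.abs(d - params.r) > delta
    return EdgePixelVector(points=P.points[keep], shape=P.shape)


def render_overlay(image: np.ndarray, detections: list[Detection],
                   color=(255, 0, 0)) -> np.ndarray:
    """Copy of the image with each detection's circumference marked.

    Grayscale input is promoted to RGB so the mark colour is visible.
    """
    img = np.asarray(image)
    if img.ndim == 2:
        out = np.stack([img] * 3, axis=-1).astype(np.uint8)
    else:
        out = img.astype(np.uint8).copy()
    for det in detections:
        try:
            sample = sample_circumference(det.params, out.shape[:2])
        except EmptySampleError:
            continue
        out[sample.points[:, 1], sample.points[:, 0]] = color
    return out


class DetectionResults:
    """Results of one detection fit: estimates, diagnostics, presentation."""

    def __init__(self, model: "CircleDetector", detections: list[Detection],
                 seed: int, source: str | None = None):
        self.model = model
        self.detections = list(detections)
        self.seed = int(seed)
        self.source = source
        self.config_digest = model.config.digest()

    @property
    def n_c(self) -> int:
        """Number of circles detected."""
        return len(self.detections)

    @property
    def circles(self) -> list[CircleParams]:
        return [d.params for d in self.detections]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"image": self.source or "", "order": d.order,
             "x0": d.params.x0, "y0": d.params.y0, "r": d.params.r,
             "fitness": d.fitness, "coverage": d.coverage}
            for d in self.detections
        ]
        return pd.DataFrame(rows, columns=["image", "order", "x0", "y0",
                                           "r", "fitness", "coverage"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self, path=None):
        payload = {
            "provenance": {
                "image": self.source or "",
                "config_digest": self.config_digest,
                "seed": self.seed,
            },
            "n_c": self.n_c,
            "detections": [
                {"order": d.order, "x0": d.params.x0, "y0": d.params.y0,
                 "r": d.params.r, "fitness": d.fitness, "coverage": d.coverage}
                for d in self.detections
            ],
        }
        if path is None:
            return payload
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2)
        return payload

    def overlay(self, color=(255, 0, 0)) -> np.ndarray:
        return render_overlay(self.model.image, self.detections, color=color)

    def plot(self, ax=None):
        """Show the image with detected circles drawn on top."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.imshow(self.model.image, cmap="gray", vmin=0, vmax=255)
        theta = np.linspace(0, 2 * np.pi, 256)
        for d in self.detections:
            ax.plot(d.params.x0 + d.params.r * np.cos(theta),
                    d.params.y0 + d.params.r * np.sin(theta), "r-", lw=1)
            ax.annotate(str(d.order), (d.params.x0, d.params.y0),
                        color="red", ha="center", va="center")
        ax.set_axis_off()
        return ax

    def summary(self) -> str:
        lines = [
            "Leukocyte circle detection (plant-growth-simulation search)",
            f"  image: {self.source or '<array>'}",
            f"  seed: {self.seed}   config: {self.config_digest}",
            f"  edge pixels: {self.model.edge_vector_.n_p}"
            f"   circles detected: {self.n_c}",
            "",
        ]
        frame = self.to_frame().drop(columns=["image"])
        if len(frame):
            lines.append(frame.to_string(index=False,
                                         float_format=lambda v: f"{v:.2f}"))
        else:
            lines.append("  (no detection)")
        return "\n".join(lines)


class CircleDetector:
    """Circle-detection model over a smear image.

    Construction runs preprocessing eagerly; the segmented mask and the
    edge-pixel vector are available as ``mask_`` and ``edge_vector_``.
    ``fit(seed)`` runs the seeded stochastic search.
    """

    def __init__(self, image: np.ndarray, config: RunConfig | None = None,
                 mask: np.ndarray | None = None, source: str | None = None):
        self.config = config or RunConfig()
        self.config.validate()
        img = np.asarray(image)
        if img.ndim == 3:
            img = to_grayscale(img)
        if img.ndim != 2 or img.shape[0] < 3 or img.shape[1] < 3:
            raise ValueError("image must be at least 3 x 3, single channel or RGB")
        self.image = img
        self.source = source
        pp = self.config.preprocess
        work = img
        if pp.median_filter > 1:
            # standard smear despeckle: kills impulse noise before thresholding
            from scipy.ndimage import median_filter

            work = median_filter(img, size=pp.median_filter)
        if mask is not None:
            m = np.asarray(mask)
            if m.shape != img.shape:
                raise ValueError("mask dimensions must match the image")
            self.mask_ = (m > 0).astype(np.uint8)
        else:
            self.mask_ = segment_histogram_threshold(
                work, threshold=pp.threshold, foreground=pp.foreground,
                on_constant=pp.on_constant)
        if pp.edge_method == "morph":
            self.edge_vector_ = morphological_edge_map(self.mask_)
        else:
            rendering = (self.mask_ * 255).astype(np.uint8)
            self.edge_vector_ = canny_edges(
                rendering, low=pp.canny_low, high=pp.canny_high,
                sigma=pp.canny_sigma)

    @classmethod
    def from_file(cls, path, config: RunConfig | None = None) -> "CircleDetector":
        return cls(read_image(path), config=config, source=str(path))

    # -- candidate generation ------------------------------------------------

    def _r_limits(self) -> tuple[float, float]:
        det = self.config.detector
        r_max = det.r_max
        if r_max is None:
            h, w = self.image.shape
            r_max = min(w, h) / 2.0
        return det.r_min, r_max

    def _make_candidate(self, P, edges, e1, e2, e3) -> CandidateCircle | None:
        r_min, r_max = self._r_limits()
        try:
            cand = candidate_from_indices(P, e1, e2, e3, r_min, r_max)
        except DegenerateTripleError:
            return None
        if cand is None:
            return None
        try:
            fitness(cand, edges, self.mask_)
        except EmptySampleError:
            return None
        return cand

    def _random_triple(self, rng, n):
        return tuple(int(v) for v in rng.choice(n, size=3, replace=False))

    def _initializer(self, P: EdgePixelVector, edges: EdgeSet):
        k = self.config.engine.k

        def init(rng: np.random.Generator):
            out = []
            attempts = 0
            n = len(P)
            while len(out) < k and attempts < 60 * k:
                attempts += 1
                cand = self._make_candidate(P, edges, *self._random_triple(rng, n))
                if cand is not None:
                    out.append(cand)
            return out

        return init

    def _proposer(self, P: EdgePixelVector, edges: EdgeSet):
        eng = self.config.engine
        n = len(P)
        w = eng.w if eng.w is not None else max(1, round(0.02 * n))

        def propose(parent: CandidateCircle, rng: np.random.Generator):
            out = []
            for _ in range(eng.q):
                if rng.uniform() < eng.p_explore:
                    triple = self._random_triple(rng, n)
                else:
                    triple = tuple(
                        int((e + rng.integers(-w, w + 1)) % n)
                        for e in (parent.e1, parent.e2, parent.e3))
                    if len(set(triple)) != 3:
                        triple = self._random_triple(rng, n)
                cand = self._make_candidate(P, edges, *triple)
                if cand is not None:
                    out.append(cand)
            return out

        return propose

    # -- fitting -------------------------------------------------------------

    def fit(self, seed: int = 0) -> DetectionResults:
        """Run multi-circle detection; deterministic for a fixed seed."""
        det = self.config.detector
        eng = self.config.engine
        master = np.random.default_rng(seed)
        P = self.edge_vector_
        detections: list[Detection] = []

        while len(P) >= max(det.min_edge_points, 3) and len(detections) < det.max_circles:
            edges = EdgeSet(P, tolerance=det.edge_tolerance)
            run_seed = int(master.integers(2**31))
            try:
                state = pgsa.run(self._proposer(P, edges),
                                 self._initializer(P, edges),
                                 config=eng, seed=run_seed)
            except pgsa.InitializationError:
                break
            best: CandidateCircle = state.best.candidate
            if best.breakdown.coverage < det.alpha:
                break
            detections.append(Detection(
                params=best.params, fitness=float(best.fitness),
                coverage=float(best.breakdown.coverage),
                order=len(detections) + 1))
            survivors = erase_support(P, best.params, det.delta)
            if len(survivors) >= len(P):
                # guarantee progress: drop the anchor triple outright
                keep = np.ones(len(P), dtype=bool)
                keep[[best.e1, best.e2, best.e3]] = False
                survivors = EdgePixelVector(points=P.points[keep], shape=P.shape)
            P = survivors

        return DetectionResults(self, detections, seed=seed, source=self.source)


def detect(image: np.ndarray, config: RunConfig | None = None,
           seed: int = 0, source: str | None = None) -> DetectionResults:
    """Functional one-shot wrapper: build the model and fit it."""
    return CircleDetector(image, config=config, source=source).fit(seed=seed)
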