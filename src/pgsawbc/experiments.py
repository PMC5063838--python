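"""Self-contained validation experiments for the detector.

These routines reproduce, at desk scale on synthetic scenes, the study
protocol the detector is built for: morphactin-allocation consistency,
geometry agreement with an independent construction, roulette fidelity,
parameter recovery on clean scenes, ideal-condition metrics, occlusion
tolerance, and noise-degradation ordering. Each is a pure function of a
seed, so every number it returns is reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .circle import circumcircle
from .config import DetectorConfig, RunConfig
from .detector import detect
from .evaluation import match, noise_bench, report
from .pgsa import PlantState, allocate_concentrations, select_preferential_node
from .synthetic import CellSpec, SceneSpec, _base_scene, render_scene

__all__ = [
    "concentration_sum_deviation",
    "circumcircle_oracle_error",
    "roulette_frequency",
    "single_circle_recovery",
    "three_cell_scene",
    "ideal_condition_metrics",
    "occlusion_tolerance",
    "noise_ordering",
]


@dataclass
class _Stub:
    """Opaque candidate for engine-level experiments."""

    ident: int
    fitness: float

    @property
    def key(self):
        return self.ident


def concentration_sum_deviation(n_trials: int = 1000, seed: int = 0) -> float:
    """Max |sum C_Ti - 1| over randomized eligible node sets.

    Each trial draws n in {1..50} node fitnesses uniformly below a root
    fitness of 1.0, allocates concentrations, sums them, then retires a
    random node (reallocation) and sums again.
    """
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_trials):
        n = int(rng.integers(1, 51))
        fits = rng.uniform(-10.0, 1.0 - 1e-12, size=n)
        state = PlantState(root_fitness=1.0)
        for i, f in enumerate(fits):
            state.add_node(_Stub(ident=i, fitness=float(f)), origin="trunk")
        allocate_concentrations(state)
        total = sum(m.concentration for m in state.alive_nodes)
        worst = max(worst, abs(total - 1.0))
        if n > 1:  # reallocation after retiring one node
            victim = state.alive_nodes[int(rng.integers(n))]
            victim.alive = False
            victim.concentration = 0.0
            allocate_concentrations(state)
            total = sum(m.concentration for m in state.alive_nodes)
            worst = max(worst, abs(total - 1.0))
    return worst


def circumcircle_oracle_error(n_triples: int = 10_000, seed: int = 0) -> float:
    """Max relative disagreement between the determinant construction and
    an independent perpendicular-bisector solve, over random triples."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    done = 0
    while done < n_triples:
        pts = rng.uniform(0.0, 512.0, size=(3, 2))
        u, v = pts[1] - pts[0], pts[2] - pts[0]
        area2 = u[0] * v[1] - u[1] * v[0]
        if abs(area2) < 1.0:        # skip near-degenerate draws
            continue
        c = circumcircle(*pts)
        a = np.array([pts[1] - pts[0], pts[2] - pts[0]])
        b = np.array([(pts[1] @ pts[1] - pts[0] @ pts[0]) / 2.0,
                      (pts[2] @ pts[2] - pts[0] @ pts[0]) / 2.0])
        center = np.linalg.solve(a, b)
        radius = float(np.linalg.norm(center - pts[0]))
        scale = max(1.0, abs(center[0]), abs(center[1]), radius)
        err = max(abs(c.x0 - center[0]), abs(c.y0 - center[1]),
                  abs(c.r - radius)) / scale
        worst = max(worst, err)
        done += 1
    return worst


def roulette_frequency(n_draws: int = 10_000, seed: int = 0) -> float:
    """Empirical selection frequency of the 0.75-concentration node."""
    state = PlantState(root_fitness=10.0)
    state.add_node(_Stub(ident=0, fitness=4.0), origin="trunk")   # deficit 6
    state.add_node(_Stub(ident=1, fitness=8.0), origin="trunk")   # deficit 2
    allocate_concentrations(state)
    rng = np.random.default_rng(seed)
    hits = sum(select_preferential_node(state, float(b)) == 0
               for b in rng.uniform(size=n_draws))
    return hits / n_draws


def _single_cell_scene(rng: np.random.Generator) -> tuple:
    x = float(rng.uniform(60, 300))
    y = float(rng.uniform(60, 300))
    r = float(rng.uniform(25, 45))
    return render_scene(SceneSpec(cells=(CellSpec(center=(x, y), radius=r),)))


def single_circle_recovery(n_scenes: int = 20, seed: int = 0,
                           config: RunConfig | None = None) -> tuple[int, int]:
    """(successes, n_scenes) on clean single-circle scenes.

    Success: some detection with centre and radius error both <= 2 px.
    """
    config = config or RunConfig()
    master = np.random.default_rng(seed)
    ok = 0
    for _ in range(n_scenes):
        img, truth = _single_cell_scene(master)
        res = detect(img, config=config, seed=int(master.integers(2**31)))
        t = truth.circles[0]
        ok += any(
            math.hypot(d.params.x0 - t.x0, d.params.y0 - t.y0) <= 2.0
            and abs(d.params.r - t.r) <= 2.0
            for d in res.detections)
    return ok, n_scenes


def three_cell_scene(seed: int = 1):
    """Clean 360 x 363 scene with 3 well-separated cells (radii 25-45 px)."""
    rng = np.random.default_rng(seed)
    return render_scene(_base_scene(rng))


def ideal_condition_metrics(seed: int = 1,
                            config: RunConfig | None = None) -> tuple[float, float]:
    """(precision %, sensitivity %) on a clean three-cell scene."""
    config = config or RunConfig()
    img, truth = three_cell_scene(seed)
    res = detect(img, config=config, seed=seed)
    m = match(res.circles, list(truth.circles),
              tau_c=config.eval.tau_c, tau_r=config.eval.tau_r)
    rep = report(m)
    return rep.precision_pct, rep.sensitivity_pct


def _occlusion_run(hidden_fraction: float, n_seeds: int, seed: int) -> int:
    """Successful localizations of a 68-%-style occluded cell over seeds."""
    alpha = max(0.05, (1.0 - hidden_fraction) - 0.05)
    cfg = RunConfig(detector=DetectorConfig(alpha=alpha))
    master = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_seeds):
        start = float(master.uniform(0.0, 2.0 * math.pi))
        img, truth = render_scene(SceneSpec(cells=(
            CellSpec(center=(180.0, 180.0), radius=35.0,
                     hidden_fraction=hidden_fraction, hidden_start=start),)))
        res = detect(img, config=cfg, seed=int(master.integers(2**31)))
        m = match(res.circles, list(truth.circles), tau_c=5.0, tau_r=0.2)
        hits += m.tp >= 1
    return hits


def occlusion_tolerance(fractions=(0.68, 0.60, 0.50, 0.40),
                        n_seeds: int = 20, seed: int = 0) -> tuple[float, dict]:
    """Largest tested hidden fraction still detected in a majority of runs.

    Fractions are tried in descending order; the first with a majority of
    successful localizations is returned (0.0 if none), together with the
    per-fraction success counts actually measured.
    """
    counts: dict[float, int] = {}
    for frac in sorted(fractions, reverse=True):
        hits = _occlusion_run(frac, n_seeds, seed)
        counts[frac] = hits
        if hits > n_seeds // 2:
            return frac, counts
    return 0.0, counts


def noise_ordering(n_per_level: int = 10, seed: int = 0,
                   config: RunConfig | None = None) -> pd.DataFrame:
    """TPR per corruption level (clean, Gaussian 10/15, s&p 10/15 %)."""
    config = config or RunConfig()
    return noise_bench(config, n_per_level=n_per_level, seed=seed)
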