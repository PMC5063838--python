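"""Synthetic blood-smear scenes with exact ground truth.

Real smear images show dark-stained leukocyte nuclei on a bright
background, surrounded by paler red-cell discs that act as distractors.
The generator emulates that geometry on a 360 x 363 canvas: a bright
background (200), annular red-cell-like distractors (150), and circular
leukocytes (60 dark / 90 "bright" variant), optionally deformed by a
low-order sinusoidal radial perturbation and occluded along a contiguous
boundary arc. Ground truth (centre, radius per cell) is exact by
construction and is never altered by the noise operators.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .circle import CircleParams

__all__ = [
    "CellSpec",
    "DistractorSpec",
    "SceneSpec",
    "GroundTruth",
    "NoiseSpec",
    "render_scene",
    "add_noise",
    "generate_suite",
    "PROFILES",
]

#: Default canvas, matching the 360 x 363 px smear images the detector targets.
DEFAULT_WIDTH = 360
DEFAULT_HEIGHT = 363

#: Default intensity model (8-bit): bright background, paler red-cell
#: distractors, dark leukocyte nuclei plus a brighter leukocyte variant.
BACKGROUND = 200
DISTRACTOR_INTENSITY = 150
DARK_CELL = 60
BRIGHT_CELL = 90

#: Half-width (px) of the background band painted over an occluded arc.
OCCLUSION_BAND = 3.0


@dataclass(frozen=True)
class CellSpec:
    """One leukocyte: centre (x, y), radius, intensity, and defects.

    ``deformation`` in [0, 0.3] is the relative amplitude of a 3-lobed
    sinusoidal radial perturbation of the boundary; ``hidden_fraction``
    in [0, 1) occludes a contiguous boundary arc (starting at
    ``hidden_start`` radians) by overpainting it with background.
    """

    center: tuple[float, float]
    radius: float
    intensity: int = DARK_CELL
    deformation: float = 0.0
    deformation_phase: float = 0.0
    hidden_fraction: float = 0.0
    hidden_start: float = 0.0


@dataclass(frozen=True)
class DistractorSpec:
    """A red-cell-like disc or annulus (pale centre)."""

    center: tuple[float, float]
    radius: float
    intensity: int = DISTRACTOR_INTENSITY
    annular: bool = True
    inner_fraction: float = 0.55


@dataclass(frozen=True)
class SceneSpec:
    width: int = DEFAULT_WIDTH
    height: int = DEFAULT_HEIGHT
    background: int = BACKGROUND
    cells: tuple[CellSpec, ...] = ()
    distractors: tuple[DistractorSpec, ...] = ()

    def validate(self) -> None:
        for c in self.cells:
            x, y = c.center
            if not (0 <= x < self.width and 0 <= y < self.height):
                raise ValueError(f"cell centre {c.center} outside canvas")
            if c.radius <= 0:
                raise ValueError("cell radius must be positive")
            if not 0 <= c.hidden_fraction < 1:
                raise ValueError("hidden_fraction must be in [0, 1)")
            if not 0 <= c.deformation <= 0.3:
                raise ValueError("deformation must be in [0, 0.3]")


@dataclass(frozen=True)
class GroundTruth:
    """Exact circle list for the cells (distractors are not truth)."""

    circles: tuple[CircleParams, ...]

    def __len__(self) -> int:
        return len(self.circles)


@dataclass(frozen=True)
class NoiseSpec:
    """Image corruption: additive Gaussian or salt-and-pepper impulses.

    ``sigma`` is the Gaussian standard deviation in intensity units;
    ``fraction`` the exact proportion of pixels hit by impulses (chosen
    without replacement, set to 0 or 255 with equal probability).
    """

    kind: str = "none"                 # none | gaussian | salt_pepper
    sigma: float = 0.0
    fraction: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.kind not in ("none", "gaussian", "salt_pepper"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("fraction must be in [0, 1]")


def _radial_limit(cell: CellSpec, theta: np.ndarray) -> np.ndarray:
    """Deformed boundary radius r(theta) for a cell."""
    if cell.deformation == 0.0:
        return np.full_like(theta, cell.radius, dtype=float)
    return cell.radius * (1.0 + cell.deformation
                          * np.sin(3.0 * theta + cell.deformation_phase))


def render_scene(spec: SceneSpec) -> tuple[np.ndarray, GroundTruth]:
    """Draw background, then distractors, then cells; return image + truth.

    Occlusion overpaints, with background, the band of half-width
    ``OCCLUSION_BAND`` around the boundary over the hidden arc, so the
    hidden portion contributes no boundary contrast while the cell body
    remains (a cell overlapped by clutter, not a missing cell).
    """
    spec.validate()
    img = np.full((spec.height, spec.width), spec.background, dtype=np.uint8)
    gy, gx = np.mgrid[0:spec.height, 0:spec.width]

    for d in spec.distractors:
        dist = np.hypot(gx - d.center[0], gy - d.center[1])
        if d.annular:
            sel = (dist <= d.radius) & (dist >= d.inner_fraction * d.radius)
        else:
            sel = dist <= d.radius
        img[sel] = d.intensity

    for c in spec.cells:
        dx, dy = gx - c.center[0], gy - c.center[1]
        dist = np.hypot(dx, dy)
        theta = np.arctan2(dy, dx)
        limit = _radial_limit(c, theta)
        img[dist < limit] = c.intensity
        if c.hidden_fraction > 0.0:
            span = c.hidden_fraction * 2.0 * math.pi
            rel = np.mod(theta - c.hidden_start, 2.0 * math.pi)
            in_arc = rel <= span
            band = np.abs(dist - limit) <= OCCLUSION_BAND
            img[in_arc & band] = spec.background

    truth = GroundTruth(circles=tuple(
        CircleParams(x0=float(c.center[0]), y0=float(c.center[1]), r=float(c.radius))
        for c in spec.cells))
    return img, truth


def add_noise(image: np.ndarray, noise: NoiseSpec) -> np.ndarray:
    """Apply the corruption described by ``noise``; seeded, reproducible."""
    noise.validate()
    img = np.asarray(image)
    if noise.kind == "none" or (noise.kind == "gaussian" and noise.sigma == 0.0) \
            or (noise.kind == "salt_pepper" and noise.fraction == 0.0):
        return img.copy()
    rng = np.random.default_rng(noise.seed)
    if noise.kind == "gaussian":
        out = img.astype(np.float64) + rng.normal(0.0, noise.sigma, img.shape)
        return np.clip(np.rint(out), 0, 255).astype(np.uint8)
    # salt & pepper: exact pixel count, chosen without replacement
    out = img.copy()
    n_pix = img.size
    n_hit = int(round(noise.fraction * n_pix))
    flat_idx = rng.choice(n_pix, size=n_hit, replace=False)
    values = rng.choice([0, 255], size=n_hit)
    out.reshape(-1)[flat_idx] = values.astype(np.uint8)
    return out


# --------------------------------------------------------------------------
# Suite generation


def _place_cells(rng: np.random.Generator, n_cells: int,
                 width: int, height: int,
                 r_lo: float = 25.0, r_hi: float = 45.0,
                 min_gap: float = 12.0, max_tries: int = 200) -> list[tuple]:
    """Rejection-sample non-overlapping (centre, radius) pairs."""
    placed: list[tuple] = []
    margin = r_hi + 5
    for _ in range(max_tries):
        if len(placed) == n_cells:
            break
        r = float(rng.uniform(r_lo, r_hi))
        x = float(rng.uniform(margin, width - margin))
        y = float(rng.uniform(margin, height - margin))
        ok = all(np.hypot(x - px, y - py) >= r + pr + min_gap
                 for (px, py), pr in placed)
        if ok:
            placed.append(((x, y), r))
    return placed


def _base_scene(rng: np.random.Generator, n_cells: int = 3,
                n_distractors: int = 5, **cell_kwargs) -> SceneSpec:
    cells_geo = _place_cells(rng, n_cells, DEFAULT_WIDTH, DEFAULT_HEIGHT)
    cells = tuple(CellSpec(center=c, radius=r, **cell_kwargs) for c, r in cells_geo)
    distractors = []
    for _ in range(n_distractors):
        for _ in range(100):
            r = float(rng.uniform(20, 30))
            x = float(rng.uniform(r, DEFAULT_WIDTH - r))
            y = float(rng.uniform(r, DEFAULT_HEIGHT - r))
            if all(np.hypot(x - c.center[0], y - c.center[1]) >= r + c.radius + 8
                   for c in cells):
                distractors.append(DistractorSpec(center=(x, y), radius=r))
                break
    return SceneSpec(cells=cells, distractors=tuple(distractors))


def _profile_scene(profile: str, rng: np.random.Generator) -> tuple[SceneSpec, NoiseSpec]:
    noise = NoiseSpec()
    if profile == "clean":
        spec = _base_scene(rng)
    elif profile == "deformed":
        spec = _base_scene(rng, deformation=0.12,
                           deformation_phase=float(rng.uniform(0, 2 * math.pi)))
    elif profile == "occluded":
        spec = _base_scene(rng, n_cells=1,
                           hidden_fraction=0.68,
                           hidden_start=float(rng.uniform(0, 2 * math.pi)))
    elif profile == "noisy":
        spec = _base_scene(rng)
        noise = NoiseSpec(kind="gaussian", sigma=15.0,
                          seed=int(rng.integers(2**31)))
    else:
        raise ValueError(f"unknown profile {profile!r}")
    return spec, noise


PROFILES = ("clean", "deformed", "occluded", "noisy")


def generate_suite(
    n_images: int,
    profile: str = "clean",
    seed: int = 0,
    noise: NoiseSpec | None = None,
) -> list[tuple[np.ndarray, GroundTruth]]:
    """Reproducible batch of (image, truth) pairs for one profile.

    Per-image seeds derive from the master seed, so (profile, seed)
    fully determines the batch. An explicit ``noise`` spec overrides the
    profile's own corruption (its seed field is re-derived per image).
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    if profile not in PROFILES:
        raise ValueError(f"unknown profile {profile!r}; choose from {PROFILES}")
    master = np.random.SeedSequence(seed)
    out = []
    for child in master.spawn(n_images):
        rng = np.random.default_rng(child)
        spec, prof_noise = _profile_scene(profile, rng)
        img, truth = render_scene(spec)
        eff = noise if noise is not None else prof_noise
        if eff.kind != "none":
            eff = replace(eff, seed=int(rng.integers(2**31)))
            img = add_noise(img, eff)
        out.append((img, truth))
    return out
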