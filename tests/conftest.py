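import numpy as np
import pytest

from pgsawbc import CellSpec, SceneSpec, render_scene


@pytest.fixture
def single_cell_scene():
    """Clean 360x363 scene with one leukocyte disc (r = 30 at (180, 180))."""
    spec = SceneSpec(cells=(CellSpec(center=(180.0, 180.0), radius=30.0),))
    img, truth = render_scene(spec)
    return img, truth


@pytest.fixture
def rng():
    return np.random.default_rng(20231)


def brute_force_disc(shape, x0, y0, r):
    """Boolean interior by scanning every pixel (independent oracle)."""
    h, w = shape
    out = np.zeros(shape, dtype=bool)
    for y in range(h):
        for x in range(w):
            if np.hypot(x - x0, y - y0) < r:
                out[y, x] = True
    return out


def brute_force_ring(shape, x0, y0, r, band=0.5):
    """Boolean circumference band |dist - r| <= band by full scan."""
    h, w = shape
    out = np.zeros(shape, dtype=bool)
    for y in range(h):
        for x in range(w):
            if abs(np.hypot(x - x0, y - y0) - r) <= band:
                out[y, x] = True
    return out
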