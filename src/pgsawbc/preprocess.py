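"""Image pre-processing: segmentation and edge-pixel extraction.

A smear image is reduced to two products before detection: a binary mask
separating the leukocyte class from everything else (histogram thresholding),
and an ordered vector of edge-pixel coordinates P. Candidate circles are
index triples into P, so P's ordering (row-major) is part of the contract.

Coordinates are 0-based with x = column and y = row, origin top-left.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from PIL import Image
from scipy import ndimage
from skimage import feature as skfeature
from skimage.filters import threshold_otsu

__all__ = [
    "EdgePixelVector",
    "to_grayscale",
    "segment_histogram_threshold",
    "morphological_edge_map",
    "canny_edges",
    "read_image",
    "write_mask_png",
    "DegenerateHistogramError",
]

#: 3x3 cross (4-connectivity) structuring element used for the erosion step.
CROSS = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)

#: BT.601 luma weights for RGB -> intensity conversion.
LUMA_WEIGHTS = (0.299, 0.587, 0.114)


class DegenerateHistogramError(ValueError):
    """Auto-thresholding requested on a constant (single-level) image."""


@dataclass(frozen=True)
class EdgePixelVector:
    """Ordered edge-pixel coordinates P = {p_1 ... p_Np}.

    ``points`` is an (N_p, 2) integer array of (x, y) pairs in row-major
    image order; ``shape`` is the (height, width) of the source image.
    """

    points: np.ndarray
    shape: tuple[int, int]

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=np.int64).reshape(-1, 2)
        object.__setattr__(self, "points", pts)
        if len(pts):
            h, w = self.shape
            if (pts[:, 0].min() < 0 or pts[:, 0].max() >= w
                    or pts[:, 1].min() < 0 or pts[:, 1].max() >= h):
                raise ValueError("edge points out of image bounds")

    @property
    def n_p(self) -> int:
        return len(self.points)

    def __len__(self) -> int:
        return len(self.points)

    def to_bool_image(self) -> np.ndarray:
        """Render P as a boolean (height, width) membership image."""
        img = np.zeros(self.shape, dtype=bool)
        if len(self.points):
            img[self.points[:, 1], self.points[:, 0]] = True
        return img

    @classmethod
    def from_bool_image(cls, img: np.ndarray) -> "EdgePixelVector":
        """Collect True pixels in row-major order into a vector."""
        ys, xs = np.nonzero(np.asarray(img, dtype=bool))
        return cls(points=np.column_stack([xs, ys]), shape=img.shape)

    def to_csv(self, path) -> None:
        np.savetxt(path, self.points, fmt="%d", delimiter=",", header="x,y", comments="")


def _as_gray(image: np.ndarray) -> np.ndarray:
    arr = np.asarray(image)
    if arr.ndim != 2:
        raise ValueError(f"expected a single-channel image, got shape {arr.shape}")
    return arr


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Convert an (H, W, 3) RGB image to 8-bit intensity via BT.601 luma."""
    arr = np.asarray(image)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"expected an (H, W, 3) RGB image, got shape {arr.shape}")
    w = np.asarray(LUMA_WEIGHTS)
    gray = arr.astype(np.float64) @ w
    return np.clip(np.rint(gray), 0, 255).astype(np.uint8)


def segment_histogram_threshold(
    gray: np.ndarray,
    threshold: int | None = None,
    foreground: str = "dark",
    on_constant: str = "warn",
) -> np.ndarray:
    """Threshold an intensity image into a {0, 1} leukocyte mask.

    With ``threshold=None`` the cut is placed by Otsu's maximal
    between-class-variance rule on the 256-bin histogram. ``foreground``
    selects which side of the cut is the cell class: stained leukocyte
    nuclei are darker than the smear background, so the default is
    ``"dark"`` (pixels <= threshold become 1).
    """
    gray = _as_gray(gray)
    if foreground not in ("dark", "bright"):
        raise ValueError("foreground must be 'dark' or 'bright'")
    if threshold is None:
        if gray.min() == gray.max():
            if on_constant == "error":
                raise DegenerateHistogramError(
                    "constant image: automatic histogram threshold is undefined")
            warnings.warn("constant image: returning all-background mask",
                          stacklevel=2)
            return np.zeros(gray.shape, dtype=np.uint8)
        thr = float(threshold_otsu(gray, nbins=256))
    else:
        thr = float(threshold)
    if foreground == "dark":
        mask = gray <= thr
    else:
        mask = gray > thr
    return mask.astype(np.uint8)


def morphological_edge_map(mask: np.ndarray) -> EdgePixelVector:
    """Extract the one-pixel boundary ring of a binary mask.

    The mask is eroded with a 3x3 cross and inverted; pixels that are
    foreground in both the original mask and the inverted erosion — i.e.
    foreground pixels removed by erosion — form the boundary. An empty
    mask yields an empty vector.
    """
    m = np.asarray(mask).astype(bool)
    if m.ndim != 2:
        raise ValueError("mask must be 2-D")
    eroded = ndimage.binary_erosion(m, structure=CROSS, border_value=0)
    edge = m & ~eroded
    return EdgePixelVector.from_bool_image(edge)


def canny_edges(
    gray: np.ndarray,
    low: float | None = None,
    high: float | None = None,
    sigma: float = 1.0,
) -> EdgePixelVector:
    """Canny edge pixels of an intensity image, collected row-major.

    When thresholds are omitted they follow the median rule
    (low = 0.66 * median, high = 1.33 * median of the intensities); if the
    median is degenerate (0, as on a mostly-background 0/255 rendering)
    the detector falls back to its quantile defaults.
    """
    gray = _as_gray(gray).astype(np.float64)
    if (low is None) != (high is None):
        raise ValueError("low and high must be given together")
    if low is not None:
        if low <= 0 or high <= 0:
            raise ValueError("canny thresholds must be positive")
        if not low < high:
            raise ValueError("canny thresholds must satisfy low < high")
    else:
        med = float(np.median(gray))
        if med > 0:
            low, high = 0.66 * med, 1.33 * med
    edges = skfeature.canny(gray, sigma=sigma, low_threshold=low, high_threshold=high)
    return EdgePixelVector.from_bool_image(edges)


def read_image(path) -> np.ndarray:
    """Read a PNG/JPG as uint8; grayscale stays 2-D, colour becomes (H, W, 3)."""
    with Image.open(path) as img:
        if img.mode in ("L", "I;16", "I"):
            arr = np.asarray(img.convert("L"))
        else:
            arr = np.asarray(img.convert("RGB"))
    return arr.astype(np.uint8)


def write_mask_png(mask: np.ndarray, path) -> None:
    """Write a {0,1} mask as a 0/255 grayscale PNG."""
    Image.fromarray((np.asarray(mask) > 0).astype(np.uint8) * 255, mode="L").save(path)
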