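"""Supervision rasters derived from dot annotations.

Counting networks are trained against rasters built from point annotations
(one dot per plant).  Three rasters are derived here:

* a **density map** — a sum of isotropic 2-D Gaussians, one per dot, whose
  integral approximates the object count;
* a **local count map** — the density map aggregated over non-overlapping
  ``h x w`` pixel patches (stride equals patch size), so each cell holds the
  expected number of objects inside that patch;
* a **pseudo foreground mask** — the density map thresholded at ``t_c``,
  which stands in for pixel-level segmentation labels that dot-annotated
  datasets do not have.

Gaussian kernels are evaluated at pixel centres inside a square support
window cut at 4σ (contributions beyond 4σ are below 3.4e-4 of the peak) and
are truncated, not renormalised, at image borders.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DotAnnotationSet",
    "DensityMap",
    "LocalCountMap",
    "ForegroundMask",
    "make_density_map",
    "make_local_count_map",
    "make_foreground_mask",
    "downsample_mask",
    "gaussian_peak",
    "default_threshold",
    "KERNEL_SUPPORT_SIGMAS",
]

#: Gaussian support half-width in units of sigma.
KERNEL_SUPPORT_SIGMAS = 4.0


@dataclass(frozen=True)
class DotAnnotationSet:
    """Per-image plant-centre annotations.

    Points use 0-based ``(x, y)`` pixel coordinates, x rightward and y
    downward; ``image_size`` is ``(H, W)``.
    """

    image_id: str
    points: np.ndarray  # (n, 2) float array of (x, y)
    image_size: tuple[int, int]

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=np.float64).reshape(-1, 2)
        object.__setattr__(self, "points", pts)
        H, W = self.image_size
        for k, (x, y) in enumerate(pts):
            if not (0 <= x < W and 0 <= y < H):
                raise ValueError(
                    f"dot annotation out of bounds: image {self.image_id!r}, "
                    f"point {k} at ({x}, {y}) outside {H}x{W} image"
                )

    def __len__(self) -> int:
        return self.points.shape[0]


@dataclass(frozen=True)
class DensityMap:
    values: np.ndarray  # (H, W), objects per pixel
    sigma: float

    @property
    def total(self) -> float:
        return float(self.values.sum())


@dataclass(frozen=True)
class LocalCountMap:
    values: np.ndarray  # (H//h, W//w), objects per patch
    patch: tuple[int, int]

    @property
    def total(self) -> float:
        return float(self.values.sum())


@dataclass(frozen=True)
class ForegroundMask:
    values: np.ndarray  # (H, W) of {0, 1}
    threshold: float = field(default=0.0)


def gaussian_peak(sigma: float) -> float:
    """Peak value 1/(2πσ²) of a unit-mass isotropic 2-D Gaussian."""
    return 1.0 / (2.0 * np.pi * sigma * sigma)


def default_threshold(sigma: float, fraction: float = 0.05) -> float:
    """Default mask threshold: ``fraction`` of the single-kernel peak.

    The fraction is adjusted per dataset against the empirical object size so
    that each object is fully covered by its mask disk (radius
    ``sqrt(2 σ² ln(1/fraction))``).
    """
    return fraction * gaussian_peak(sigma)


def make_density_map(dots: DotAnnotationSet, sigma: float) -> DensityMap:
    """Sum of per-dot Gaussian kernels evaluated at pixel centres.

    Each annotated point contributes an isotropic Gaussian of variance
    ``sigma**2`` centred on the point; kernels are cut at a square 4σ window
    and truncated without renormalisation at image borders, so the map total
    is close to — but, for dots near borders, slightly below — the dot count.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    H, W = dots.image_size
    out = np.zeros((H, W), dtype=np.float64)
    if len(dots) == 0:
        return DensityMap(out, float(sigma))

    r = int(np.ceil(KERNEL_SUPPORT_SIGMAS * sigma))
    norm = gaussian_peak(sigma)
    inv2s2 = 1.0 / (2.0 * sigma * sigma)
    for x, y in dots.points:
        x0, x1 = int(np.ceil(x - r)), int(np.floor(x + r))
        y0, y1 = int(np.ceil(y - r)), int(np.floor(y + r))
        x0c, x1c = max(x0, 0), min(x1, W - 1)
        y0c, y1c = max(y0, 0), min(y1, H - 1)
        if x0c > x1c or y0c > y1c:
            continue
        xs = np.arange(x0c, x1c + 1, dtype=np.float64)
        ys = np.arange(y0c, y1c + 1, dtype=np.float64)
        gx = np.exp(-((xs - x) ** 2) * inv2s2)
        gy = np.exp(-((ys - y) ** 2) * inv2s2)
        out[y0c : y1c + 1, x0c : x1c + 1] += norm * np.outer(gy, gx)
    return DensityMap(out, float(sigma))


def make_local_count_map(density: DensityMap, h: int, w: int) -> LocalCountMap:
    """Aggregate a density map over a non-overlapping ``h x w`` patch grid.

    Equivalent to convolving with an all-ones ``h x w`` kernel at strides
    ``(h, w)``.  Trailing rows/columns that do not fill a complete patch are
    dropped (with a warning), matching a stride-``h/w`` convolution without
    padding.
    """
    if h < 1 or w < 1:
        raise ValueError("patch size must be >= 1")
    H, W = density.values.shape
    if h > H or w > W:
        raise ValueError(f"patch {h}x{w} larger than map {H}x{W}")
    Hb, Wb = H // h, W // w
    if H % h or W % w:
        warnings.warn(
            f"map size {H}x{W} not divisible by patch {h}x{w}; "
            "trailing partial blocks dropped",
            stacklevel=2,
        )
    v = density.values[: Hb * h, : Wb * w]
    cells = v.reshape(Hb, h, Wb, w).sum(axis=(1, 3))
    return LocalCountMap(cells, (h, w))


def make_foreground_mask(density: DensityMap, t_c: float) -> ForegroundMask:
    """Binarise a density map: pixel is foreground iff density >= ``t_c``."""
    if t_c < 0:
        raise ValueError("threshold t_c must be >= 0")
    return ForegroundMask((density.values >= t_c).astype(np.uint8), float(t_c))


def downsample_mask(mask: ForegroundMask, factor: int) -> ForegroundMask:
    """Max-pool a binary mask by ``factor`` (any-pixel-set semantics).

    Used to bring the full-resolution pseudo mask down to the 1/8-resolution
    grid of the segmentation branch while keeping every object covered.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if factor == 1:
        return ForegroundMask(mask.values.copy(), mask.threshold)
    H, W = mask.values.shape
    Hb, Wb = H // factor, W // factor
    if H % factor or W % factor:
        warnings.warn(
            f"mask size {H}x{W} not divisible by {factor}; "
            "trailing partial blocks dropped",
            stacklevel=2,
        )
    v = mask.values[: Hb * factor, : Wb * factor]
    pooled = v.reshape(Hb, factor, Wb, factor).max(axis=(1, 3))
    return ForegroundMask(pooled.astype(np.uint8), mask.threshold)
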