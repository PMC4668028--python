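"""Multi-scale Hessian-eigenvalue features.

Second image derivatives are taken by convolution with second derivatives of
a normalized Gaussian at scale sigma (x = column direction, y = row
direction; kernels truncated at radius ceil(4 sigma); reflect boundary).
At each pixel the 2x2 Hessian

    H = [[I_xx, I_xy],
         [I_xy, I_yy]]

has eigenvalues ordered so that |lambda1| <= |lambda2|.  The per-scale
feature is (lambda1, lambda2, ||H||_F, R) with R = |lambda1| / |lambda2|
(R = 0 when lambda2 = 0): a bright blob gives two strongly negative
eigenvalues and R near 1; a bright ridge gives lambda1 near 0, lambda2
strongly negative, R near 0.  Features from multiple scales are concatenated
so that microcalcifications of different sizes respond at some scale.

No gamma-normalization is applied across scales: the raw derivative-of-
Gaussian responses are used and the downstream classifier absorbs any
scale-dependent magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage

from .io import MammogramImage


class ScaleTooLargeError(ValueError):
    """The truncated kernel would exceed the image extent."""


@dataclass(frozen=True)
class ScaleFeature:
    lambda1: float
    lambda2: float
    frob: float
    ratio: float
    sigma: float

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.lambda1, self.lambda2, self.frob, self.ratio)


def _check_scale(image: MammogramImage, sigma: float) -> None:
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    radius = int(np.ceil(4.0 * sigma))
    if 2 * radius + 1 > min(image.shape):
        raise ScaleTooLargeError(
            f"kernel radius {radius} exceeds image extent {image.shape}"
        )


def hessian_at_scale(
    image: MammogramImage, sigma: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return (I_xx, I_xy, I_yy) at scale sigma, each the full-image
    convolution with the matching second derivative-of-Gaussian kernel."""
    _check_scale(image, sigma)
    truncate = np.ceil(4.0 * sigma) / sigma
    kw = dict(sigma=sigma, mode="reflect", truncate=truncate)
    ixx = ndimage.gaussian_filter(image.pixels, order=(0, 2), **kw)
    ixy = ndimage.gaussian_filter(image.pixels, order=(1, 1), **kw)
    iyy = ndimage.gaussian_filter(image.pixels, order=(2, 0), **kw)
    return ixx, ixy, iyy


def _eigs(ixx: np.ndarray, ixy: np.ndarray, iyy: np.ndarray):
    """Closed-form eigenvalues of symmetric 2x2 grids, ordered |l1| <= |l2|."""
    tr = ixx + iyy
    disc = np.sqrt((ixx - iyy) ** 2 + 4.0 * ixy**2)
    ea = 0.5 * (tr + disc)
    eb = 0.5 * (tr - disc)
    swap = np.abs(ea) > np.abs(eb)
    l1 = np.where(swap, eb, ea)
    l2 = np.where(swap, ea, eb)
    frob = np.sqrt(l1**2 + l2**2)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(l2 != 0, np.abs(l1) / np.abs(l2), 0.0)
    return l1, l2, frob, ratio


def eigen_features(
    ixx: np.ndarray,
    ixy: np.ndarray,
    iyy: np.ndarray,
    pixel: tuple[int, int],
    sigma: float,
) -> ScaleFeature:
    r, c = pixel
    l1, l2, frob, ratio = _eigs(
        np.asarray(ixx[r, c]), np.asarray(ixy[r, c]), np.asarray(iyy[r, c])
    )
    return ScaleFeature(
        lambda1=float(l1), lambda2=float(l2), frob=float(frob), ratio=float(ratio),
        sigma=float(sigma),
    )


def _check_scales(scales: Sequence[float]) -> None:
    if len(scales) == 0:
        raise ValueError("need at least one scale")
    if any(b <= a for a, b in zip(scales, scales[1:])):
        raise ValueError("scales must be strictly increasing")


def feature_vector(
    image: MammogramImage, pixel: tuple[int, int], scales: Sequence[float]
) -> np.ndarray:
    """Flattened per-pixel feature vector of length ``4 * len(scales)``,
    ordered (lambda1, lambda2, frob, ratio) per scale."""
    _check_scales(scales)
    parts = []
    for sigma in scales:
        ixx, ixy, iyy = hessian_at_scale(image, sigma)
        parts.extend(eigen_features(ixx, ixy, iyy, pixel, sigma).as_tuple())
    return np.asarray(parts, dtype=np.float64)


def feature_grid(image: MammogramImage, scales: Sequence[float]) -> np.ndarray:
    """(rows, cols, 4 * n_scales) feature array for every pixel."""
    _check_scales(scales)
    planes = []
    for sigma in scales:
        ixx, ixy, iyy = hessian_at_scale(image, sigma)
        planes.extend(_eigs(ixx, ixy, iyy))
    return np.stack(planes, axis=-1)


def feature_map(
    image: MammogramImage, mask: np.ndarray, scales: Sequence[float]
) -> tuple[np.ndarray, np.ndarray]:
    """Features for every mask pixel.

    Returns ``(coords, X)`` where ``coords`` is an (N, 2) array of (row, col)
    mask pixels in scan order and ``X`` the matching (N, 4 * n_scales)
    feature matrix; values are identical to per-pixel ``feature_vector``
    calls because both paths share the whole-image convolutions.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != image.shape:
        raise ValueError("mask shape must equal image shape")
    grid = feature_grid(image, scales)
    coords = np.argwhere(mask)
    return coords, grid[mask]
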