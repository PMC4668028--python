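"""Breast-region segmentation.

Mammograms are dominated by dark "empty space"; those pixels share very
similar intensities and therefore fall into the histogram's maximum-count
bin.  The threshold is chosen adaptively at the point of steepest drop
("maximum declivity") of the bin counts just to the right of that bin, the
binary image is smoothed by morphological dilation, and the largest
8-connected component is kept as the breast.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io import MammogramImage

_EIGHT = np.ones((3, 3), dtype=bool)


class DegenerateHistogramError(ValueError):
    """The maximum-count bin is the last bin; no declivity can be examined."""


class SegmentationError(RuntimeError):
    """Thresholding left no foreground."""


@dataclass
class BreastMask:
    mask: np.ndarray  # bool grid, same shape as the source image
    threshold_used: float

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        _, n = ndimage.label(self.mask, structure=_EIGHT)
        if n != 1:
            raise ValueError(f"breast mask must be one connected component, found {n}")


def _histogram(image: MammogramImage, n_bins: int) -> tuple[np.ndarray, np.ndarray]:
    counts, edges = np.histogram(
        image.pixels, bins=n_bins, range=(0.0, float(image.max_intensity))
    )
    return counts, edges


def adaptive_threshold(image: MammogramImage, n_bins: int = 64, n_examine: int = 8) -> float:
    """Histogram-declivity threshold.

    Builds an ``n_bins`` histogram over the full bit-depth range, finds the
    maximum-count bin ``b_max`` (empty space), and examines the declivities
    ``count(k) - count(k+1)`` for ``k = b_max .. b_max + n_examine - 1``.
    The returned threshold is the left edge of bin ``k* + 1`` where ``k*``
    maximizes the declivity (ties broken toward the smallest ``k``).
    """
    if n_bins < 4:
        raise ValueError("n_bins must be >= 4")
    if not 1 <= n_examine < n_bins:
        raise ValueError("need 1 <= n_examine < n_bins")
    counts, edges = _histogram(image, n_bins)
    b_max = int(np.argmax(counts))
    if b_max >= n_bins - 1:
        raise DegenerateHistogramError(
            "maximum-count bin is the last bin; image has no brighter tissue mode"
        )
    ks = np.arange(b_max, min(b_max + n_examine, n_bins - 1))
    declivity = counts[ks] - counts[ks + 1]
    k_star = int(ks[np.argmax(declivity)])  # np.argmax keeps the first maximum
    return float(edges[k_star + 1])


def segment_breast(
    image: MammogramImage,
    n_bins: int = 64,
    n_examine: int = 8,
    dilate_radius_px: int = 5,
) -> BreastMask:
    """Threshold (``pixel >= threshold`` is foreground), dilate with a disk
    of the given radius, and keep the largest 8-connected component."""
    if dilate_radius_px < 0:
        raise ValueError("dilate_radius_px must be >= 0")
    thr = adaptive_threshold(image, n_bins=n_bins, n_examine=n_examine)
    fg = image.pixels >= thr
    if not fg.any():
        raise SegmentationError(f"no foreground at threshold {thr}")
    if dilate_radius_px > 0:
        fg = ndimage.binary_dilation(fg, structure=_disk(dilate_radius_px))
    labels, n = ndimage.label(fg, structure=_EIGHT)
    if n == 0:
        raise SegmentationError("no connected component found")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    largest = 1 + int(np.argmax(sizes))
    return BreastMask(mask=labels == largest, threshold_used=thr)


def _disk(radius: int) -> np.ndarray:
    rr, cc = np.meshgrid(
        np.arange(-radius, radius + 1), np.arange(-radius, radius + 1), indexing="ij"
    )
    return rr**2 + cc**2 <= radius**2
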