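"""Full-image detection cascade.

Order of operations for a new image: breast segmentation -> multi-scale
Hessian features for every breast pixel (stride 1) -> random-forest
posterior, thresholded at theta_RF -> 8-connected components of the flagged
map -> one candidate per component by normalized-cross-correlation
non-maximum suppression against a 2-D Gaussian template -> DRBM patch
classification thresholded at theta_DRBM.

The candidate funnel is monotone by construction:
|final detections| <= |candidates| <= |flagged components|.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .config import PipelineConfig
from .drbm import DRBM, classify_patches
from .forest import DecisionForest, classify_candidates
from .hessian import feature_map
from .io import DetectionRecord, MammogramImage
from .segmentation import BreastMask, segment_breast

_EIGHT = np.ones((3, 3), dtype=bool)


@dataclass
class CandidateComponent:
    """One 8-connected region of RF-flagged pixels, reduced to its NMS peak."""

    pixels: np.ndarray  # (n, 2) rows of (row, col)
    peak: tuple[int, int]
    peak_score: float


@dataclass
class DetectionResult:
    records: list[DetectionRecord]
    mask: BreastMask
    rf_prob_map: np.ndarray
    candidates: list[CandidateComponent]
    n_flagged_pixels: int
    n_components: int

    @property
    def counts(self) -> dict[str, int]:
        return {
            "flagged_pixels": self.n_flagged_pixels,
            "components": self.n_components,
            "candidates": len(self.candidates),
            "final": len(self.records),
        }


def connected_components(binary_map: np.ndarray) -> list[np.ndarray]:
    """8-connected components of a binary map, each an (n, 2) coordinate
    array, ordered by first pixel in scan order."""
    labels, n = ndimage.label(np.asarray(binary_map, dtype=bool), structure=_EIGHT)
    if n == 0:
        return []
    order = np.argsort(labels.ravel(), kind="stable")
    flat = labels.ravel()[order]
    coords = np.column_stack(np.unravel_index(order, labels.shape))
    out = []
    start = np.searchsorted(flat, np.arange(1, n + 1), side="left")
    stop = np.searchsorted(flat, np.arange(1, n + 1), side="right")
    for a, b in zip(start, stop):
        out.append(coords[a:b])
    return out


def _gaussian_template(sigma: float) -> np.ndarray:
    rad = int(np.ceil(3.0 * sigma))
    rr, cc = np.meshgrid(np.arange(-rad, rad + 1), np.arange(-rad, rad + 1), indexing="ij")
    return np.exp(-(rr**2 + cc**2) / (2.0 * sigma**2))


def nms_peak(
    image: MammogramImage, pixels: np.ndarray, nms_sigma_px: float
) -> tuple[tuple[int, int], float]:
    """Pixel of the component maximizing zero-normalized cross-correlation
    between the local window and a Gaussian template of the given sigma.

    The window side is ``2 ceil(3 sigma) + 1`` (reflect-padded at image
    borders).  Ties break to the lexicographically smallest (row, col); a
    constant window scores -inf and is only selected if every pixel ties.
    """
    pixels = np.asarray(pixels)
    if len(pixels) == 0:
        raise ValueError("empty component")
    g = _gaussian_template(nms_sigma_px)
    g0 = g - g.mean()
    gnorm = np.sqrt((g0**2).sum())
    rad = g.shape[0] // 2
    padded = np.pad(image.pixels, rad, mode="symmetric")
    order = np.lexsort((pixels[:, 1], pixels[:, 0]))
    best_score = -np.inf
    best_pixel = tuple(int(v) for v in pixels[order[0]])
    for i in order:
        r, c = int(pixels[i, 0]), int(pixels[i, 1])
        win = padded[r : r + g.shape[0], c : c + g.shape[1]]
        w0 = win - win.mean()
        wnorm = np.sqrt((w0**2).sum())
        if wnorm == 0.0 or gnorm == 0.0:
            score = -np.inf
        else:
            score = float((w0 * g0).sum() / (wnorm * gnorm))
        if score > best_score:  # strict: earlier (lexicographic) pixel wins ties
            best_score = score
            best_pixel = (r, c)
    return best_pixel, best_score


def detect(
    image: MammogramImage,
    forest: DecisionForest,
    drbm: DRBM,
    config: PipelineConfig,
    image_id: str = "",
    mask: BreastMask | None = None,
) -> DetectionResult:
    """Run the full detection cascade on one image.

    ``mask`` may be supplied to skip segmentation (e.g. on phantoms with a
    known breast mask).  Deterministic given models and config.
    """
    if forest.feature_length != 4 * len(config.scales):
        raise ValueError(
            f"forest expects feature length {forest.feature_length}, config "
            f"scales give {4 * len(config.scales)}"
        )
    if drbm.n_visible != config.patch_side**2:
        raise ValueError(
            f"DRBM expects {drbm.n_visible} visible units, config patch "
            f"side {config.patch_side} gives {config.patch_side ** 2}"
        )
    if mask is None:
        mask = segment_breast(
            image,
            n_bins=config.seg_n_bins,
            n_examine=config.seg_n_examine,
            dilate_radius_px=config.seg_dilate_radius_px,
        )
    coords, X = feature_map(image, mask.mask, config.scales)
    flag_map, prob_map = classify_candidates(
        forest, coords, X, image.shape, config.theta_rf
    )
    components = connected_components(flag_map)
    candidates = []
    for comp in components:
        peak, score = nms_peak(image, comp, config.nms_sigma)
        candidates.append(CandidateComponent(pixels=comp, peak=peak, peak_score=score))
    records = classify_patches(
        drbm,
        [c.peak for c in candidates],
        image,
        config.theta_drbm,
        config.patch_side,
        image_id=image_id,
    )
    return DetectionResult(
        records=records,
        mask=mask,
        rf_prob_map=prob_map,
        candidates=candidates,
        n_flagged_pixels=int(flag_map.sum()),
        n_components=len(components),
    )
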