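"""Training-set construction and cascade training on annotated images.

Positive feature vectors / patches are taken at the annotated individual
microcalcification coordinates.  Stage-1 (RF) negatives are sampled
uniformly from the breast region excluding annotated cluster regions;
stage-2 (DRBM) negatives are the stage-1 false positives — candidate peaks
of the trained RF that do not fall near a true microcalcification — so the
second stage learns exactly the failure modes of the first.  Both negative
sets are kept the same size as the positive set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import DRBMPreset, ForestConfig, PipelineConfig
from .drbm import DRBM, DRBMTrainConfig, extract_patch
from .forest import DecisionForest, train_forest
from .hessian import feature_grid
from .pipeline import connected_components, nms_peak
from .forest import classify_candidates
from .hessian import feature_map
from .segmentation import BreastMask
from .synthetic import Phantom


def sample_negative_points(
    phantom: Phantom, n: int, rng: np.random.Generator, min_dist_px: float = 3.0
) -> np.ndarray:
    """Uniform breast-region coordinates excluding annotated cluster boxes
    and the immediate neighborhood of annotated points."""
    mask = phantom.breast_mask.copy()
    for row_min, col_min, row_max, col_max in phantom.clusters.boxes():
        r0, r1 = int(np.floor(row_min)), int(np.ceil(row_max)) + 1
        c0, c1 = int(np.floor(col_min)), int(np.ceil(col_max)) + 1
        mask[max(0, r0) : r1, max(0, c0) : c1] = False
    coords = np.argwhere(mask)
    truth = phantom.mc_points.as_array()
    picked = []
    tries = 0
    while len(picked) < n and tries < 50 * n:
        tries += 1
        r, c = coords[rng.integers(len(coords))]
        if len(truth) and np.hypot(truth[:, 0] - r, truth[:, 1] - c).min() < min_dist_px:
            continue
        picked.append((int(r), int(c)))
    return np.asarray(picked, dtype=int).reshape(-1, 2)


def build_rf_training_set(
    phantoms: list[Phantom],
    scales: tuple[float, ...],
    seed: int = 0,
    neg_per_pos: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Stack positive (annotated) and negative (random background) feature
    vectors over a list of phantoms."""
    rng = np.random.default_rng(seed)
    X_parts, y_parts = [], []
    for ph in phantoms:
        grid = feature_grid(ph.image, scales)
        pos = ph.mc_points.as_array()
        neg = sample_negative_points(ph, int(round(neg_per_pos * len(pos))), rng)
        X_parts.append(grid[pos[:, 0], pos[:, 1]])
        y_parts.append(np.ones(len(pos), dtype=np.int8))
        X_parts.append(grid[neg[:, 0], neg[:, 1]])
        y_parts.append(np.zeros(len(neg), dtype=np.int8))
    return np.concatenate(X_parts), np.concatenate(y_parts)


def stage1_candidate_peaks(
    phantom: Phantom,
    forest: DecisionForest,
    config: PipelineConfig,
) -> list[tuple[int, int]]:
    """NMS peaks of the trained RF's flagged components on one phantom."""
    coords, X = feature_map(phantom.image, phantom.breast_mask, config.scales)
    flag_map, _ = classify_candidates(forest, coords, X, phantom.image.shape, config.theta_rf)
    peaks = []
    for comp in connected_components(flag_map):
        peak, _ = nms_peak(phantom.image, comp, config.nms_sigma)
        peaks.append(peak)
    return peaks


def build_drbm_training_set(
    phantoms: list[Phantom],
    forest: DecisionForest,
    config: PipelineConfig,
    tolerance_px: float,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Positive patches at annotated coordinates; negative patches at
    stage-1 false-positive peaks (balanced to the positive count, topped up
    with random background patches if the RF produced too few)."""
    rng = np.random.default_rng(seed)
    pos_patches, neg_patches = [], []
    fp_pool: list[tuple[Phantom, tuple[int, int]]] = []
    for ph in phantoms:
        truth = ph.mc_points.as_array()
        for r, c in truth:
            pos_patches.append(extract_patch(ph.image, (r, c), config.patch_side))
        for peak in stage1_candidate_peaks(ph, forest, config):
            d = (
                np.hypot(truth[:, 0] - peak[0], truth[:, 1] - peak[1]).min()
                if len(truth)
                else np.inf
            )
            if d > tolerance_px:
                fp_pool.append((ph, peak))
    n_pos = len(pos_patches)
    if len(fp_pool) > n_pos:
        idx = rng.choice(len(fp_pool), size=n_pos, replace=False)
        fp_pool = [fp_pool[i] for i in idx]
    for ph, peak in fp_pool:
        neg_patches.append(extract_patch(ph.image, peak, config.patch_side))
    short = n_pos - len(neg_patches)
    if short > 0:
        for ph in phantoms:
            pts = sample_negative_points(ph, int(np.ceil(short / len(phantoms))), rng)
            for r, c in pts:
                neg_patches.append(extract_patch(ph.image, (r, c), config.patch_side))
        neg_patches = neg_patches[:n_pos]
    X = np.stack(pos_patches + neg_patches)
    y = np.concatenate([np.ones(n_pos, dtype=int), np.zeros(len(neg_patches), dtype=int)])
    return X, y


def calibrate_theta_rf(
    phantoms: list[Phantom],
    forest: DecisionForest,
    config: PipelineConfig,
    tolerance_px: float,
    grid: tuple[float, ...] = (0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9),
) -> float:
    """Empirical per-dataset calibration of the stage-1 threshold.

    The RF threshold trades candidate recall against candidate count, and a
    threshold that is too permissive also *merges* the flagged components
    of adjacent microcalcifications (one NMS peak then stands in for
    several).  Following the per-dataset empirical-threshold practice, the
    grid value maximizing candidate recall on the training phantoms is
    chosen, ties broken toward the fewest candidates.
    """
    from dataclasses import replace

    best = (-1.0, np.inf, config.theta_rf)
    for theta in grid:
        cfg = replace(config, theta_rf=theta)
        hit = total = n_peaks = 0
        for ph in phantoms:
            truth = ph.mc_points.as_array()
            peaks = np.asarray(stage1_candidate_peaks(ph, forest, cfg)).reshape(-1, 2)
            n_peaks += len(peaks)
            for r, c in truth:
                total += 1
                if len(peaks) and np.hypot(peaks[:, 0] - r, peaks[:, 1] - c).min() <= tolerance_px:
                    hit += 1
        recall = hit / total if total else 0.0
        if (recall, -n_peaks) > (best[0], -best[1]):
            best = (recall, n_peaks, theta)
    return best[2]


def train_cascade(
    phantoms: list[Phantom],
    pipeline_config: PipelineConfig,
    forest_config: ForestConfig,
    drbm_preset: DRBMPreset,
    seed: int = 0,
    tolerance_px: float | None = None,
    drbm_method: str = "cd",
    calibrate_theta: bool = False,
) -> tuple[DecisionForest, DRBM, PipelineConfig]:
    """Train both stages on annotated phantoms under one master seed.

    ``drbm_method`` selects the stage-2 trainer: "cd" (contrastive
    divergence on the joint) or "disc" (exact conditional-likelihood
    gradient).  With ``calibrate_theta`` the stage-1 threshold is calibrated
    on the training phantoms (see :func:`calibrate_theta_rf`); the returned
    config carries the threshold actually used.
    """
    from dataclasses import replace

    if tolerance_px is None:
        tolerance_px = 0.5 / pipeline_config.spacing_mm
    X_rf, y_rf = build_rf_training_set(phantoms, pipeline_config.scales, seed=seed + 1)
    forest = train_forest(
        X_rf, y_rf,
        n_trees=forest_config.n_trees,
        max_depth=forest_config.max_depth,
        min_node_fraction=forest_config.min_node_fraction,
        n_candidate_splits=forest_config.n_candidate_splits,
        seed=seed + 2,
    )
    if calibrate_theta:
        theta = calibrate_theta_rf(phantoms, forest, pipeline_config, tolerance_px)
        pipeline_config = replace(pipeline_config, theta_rf=theta)
    X_p, y_p = build_drbm_training_set(
        phantoms, forest, pipeline_config, tolerance_px, seed=seed + 3
    )
    model = DRBM(
        n_visible=pipeline_config.patch_side**2,
        n_hidden=drbm_preset.n_hidden,
        seed=seed + 4,
    )
    model.fit(
        X_p, y_p,
        DRBMTrainConfig(
            learning_rate=drbm_preset.learning_rate,
            n_epochs=drbm_preset.n_epochs,
            patch_side=pipeline_config.patch_side,
            seed=seed + 5,
        ),
        method=drbm_method,
    )
    return forest, model, pipeline_config
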