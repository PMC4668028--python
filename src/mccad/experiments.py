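"""End-to-end phantom study: train the cascade on synthetic phantoms and
measure detection and cluster-recovery performance on held-out phantoms.

This is the package's reproducible stand-in for a clinical evaluation: the
phantom generator defines the study conditions (512 x 512 images at
0.2 mm/pixel, ~50 microcalcifications per image, 60% of them in planted
clusters of radius 2 mm = half the pairwise-distance rule's d_c1), the
cascade is trained on independently seeded phantoms, and evaluation runs on
phantoms with fixed seeds 0..n_eval-1.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
from scipy import ndimage

from .clusters import clusters_rule1, match_cluster
from .config import ClusterRuleConfig, DRBMPreset, ForestConfig, PipelineConfig
from .evaluation import MatchingConfig, froc_curve, match_points, score_auc
from .pipeline import detect
from .synthetic import Phantom, PhantomSpec, generate_phantom
from .training import train_cascade

# the study's acquisition profile: downsampled-film-like 0.2 mm/pixel
STUDY_PIPELINE = PipelineConfig(
    scales=(0.5, 1.0, 1.5, 2.0, 2.5),
    theta_rf=0.5,
    theta_drbm=0.5,
    patch_side=9,
    spacing_mm=0.2,
)
# the study fits the DRBM by its exact conditional-likelihood gradient;
# the phantom training set is far smaller than a clinical one, and the
# discriminative objective is what classification ultimately uses
STUDY_DRBM = DRBMPreset(n_hidden=200, learning_rate=0.5, n_epochs=300)
STUDY_DRBM_METHOD = "disc"
STUDY_FOREST = ForestConfig()
STUDY_CLUSTER = ClusterRuleConfig(spacing_mm=0.2)


def study_spec(seed: int) -> PhantomSpec:
    """The study's phantom conditions; cluster radius is d_c1 / 2 so planted
    members satisfy the pairwise-distance premise of rule 1."""
    return PhantomSpec(seed=seed)


def _truth_disk_mask(phantom: Phantom, radius_px: int) -> np.ndarray:
    stamp = np.zeros(phantom.image.shape, dtype=bool)
    pts = phantom.mc_points.as_array()
    stamp[pts[:, 0], pts[:, 1]] = True
    rr, cc = np.meshgrid(
        np.arange(-radius_px, radius_px + 1),
        np.arange(-radius_px, radius_px + 1),
        indexing="ij",
    )
    disk = rr**2 + cc**2 <= radius_px**2
    return ndimage.binary_dilation(stamp, structure=disk)


def run_phantom_study(
    seed: int = 1,
    n_train: int = 6,
    n_eval: int = 20,
    collect_rf_scores: bool = True,
) -> dict:
    """Train on ``n_train`` phantoms (seeds derived from ``seed``) and
    evaluate on ``n_eval`` phantoms with fixed seeds 0..n_eval-1.

    Returns a dictionary of study metrics:

    * ``rf_pixel_roc_auc`` — pooled pixel-level ROC AUC of the RF posterior
      against ground-truth microcalcification disks,
    * ``point_sensitivity`` / ``point_fp_per_image`` — final individual
      detections matched to truth points (0.5 mm tolerance),
    * ``rule1_cluster_sensitivity`` / ``rule1_fp_clusters_per_image`` — the
      pairwise-distance rule at its native operating point (>= 3 members),
    * ``candidate_fraction_pct`` — stage-1 candidates as % of breast pixels,
    * ``funnel_violations`` — images where the cascade cardinality funnel
      |final| <= |candidates| <= |flagged components| failed (expected 0).
    """
    train_phantoms = [
        generate_phantom(study_spec(100_000 + 1000 * (seed % 1000) + i))
        for i in range(n_train)
    ]
    forest, model, pipeline_cfg = train_cascade(
        train_phantoms, STUDY_PIPELINE, STUDY_FOREST, STUDY_DRBM, seed=seed,
        drbm_method=STUDY_DRBM_METHOD, calibrate_theta=True,
    )

    matching = MatchingConfig.for_spacing(STUDY_PIPELINE.spacing_mm)
    disk_radius = max(1, int(round(matching.point_tolerance_px)))

    rf_scores, rf_labels = [], []
    cluster_dets, cluster_anns = [], []
    tp = fp = fn = 0
    candidate_fracs = []
    funnel_violations = 0
    per_image = []
    for i in range(n_eval):
        phantom = generate_phantom(study_spec(i))
        result = detect(
            phantom.image, forest, model, pipeline_cfg, image_id=f"phantom-{i}"
        )
        if collect_rf_scores:
            truth_disks = _truth_disk_mask(phantom, disk_radius)
            m = result.mask.mask
            rf_scores.append(result.rf_prob_map[m])
            rf_labels.append(truth_disks[m])
        t, f_, n_ = match_points(result.records, phantom.mc_points, matching)
        tp, fp, fn = tp + t, fp + f_, fn + n_
        counts = result.counts
        if not (
            counts["final"]
            <= counts["candidates"]
            <= counts["components"]
            <= counts["flagged_pixels"]
        ):
            funnel_violations += 1
        candidate_fracs.append(100.0 * counts["candidates"] / max(1, int(result.mask.mask.sum())))
        dets = clusters_rule1([r.point for r in result.records], STUDY_CLUSTER)
        cluster_dets.append(dets)
        cluster_anns.append(phantom.clusters)
        per_image.append(counts)

    froc = froc_curve(cluster_dets, cluster_anns, thresholds=[3.0])
    _, fp_per_image, cluster_sens = froc[0]

    out = {
        "n_train": n_train,
        "theta_rf_used": pipeline_cfg.theta_rf,
        "n_eval": n_eval,
        "point_sensitivity": tp / (tp + fn) if (tp + fn) else float("nan"),
        "point_fp_per_image": fp / n_eval,
        "rule1_cluster_sensitivity": cluster_sens,
        "rule1_fp_clusters_per_image": fp_per_image,
        "candidate_fraction_pct": float(np.mean(candidate_fracs)),
        "funnel_violations": funnel_violations,
        "per_image_counts": per_image,
        "n_annotated_clusters": sum(len(a) for a in cluster_anns),
    }
    if collect_rf_scores:
        out["rf_pixel_roc_auc"] = score_auc(
            np.concatenate(rf_scores), np.concatenate(rf_labels)
        )
    return out
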