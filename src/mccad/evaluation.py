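"""Detection evaluation: point matching, ROC / precision-recall / FROC
curves, trapezoidal AUC, and stratified cross-validation folds.

Individual detections are matched one-to-one to ground-truth points
greedily by ascending distance within a tolerance (default 0.5 mm scaled by
the pixel spacing; the tolerance is on the order of one microcalcification
radius).  Sensitivity is the fraction of true microcalcifications detected;
the ROC false-positive rate is measured against the count of
non-microcalcification pixels inside the breast mask; FROC plots cluster
sensitivity against average false-positive clusters per image, where images
without annotated clusters contribute false positives only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import rankdata

from .clusters import ClusterDetection, match_cluster
from .io import ClusterAnnotationSet, DetectionRecord, PointAnnotationSet


@dataclass
class MatchingConfig:
    point_tolerance_px: float = 5.0
    one_to_one: bool = True

    def __post_init__(self) -> None:
        if self.point_tolerance_px < 0:
            raise ValueError("point_tolerance_px must be >= 0")

    @classmethod
    def for_spacing(cls, spacing_mm: float, tolerance_mm: float = 0.5) -> "MatchingConfig":
        return cls(point_tolerance_px=tolerance_mm / spacing_mm)


@dataclass
class CurvePoint:
    threshold: float
    tp: int
    fp: int
    fn: int
    tn: int = 0

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else float("nan")

    @property
    def one_minus_specificity(self) -> float:
        total_neg = self.fp + self.tn
        return self.fp / total_neg if total_neg else float("nan")

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else float("nan")


def match_points(
    detections: Sequence[DetectionRecord] | Sequence[tuple[int, int]],
    truth: PointAnnotationSet,
    config: MatchingConfig,
) -> tuple[int, int, int]:
    """Greedy one-to-one matching by ascending detection-truth distance;
    returns (tp, fp, fn)."""
    det_pts = np.asarray(
        [d.point if isinstance(d, DetectionRecord) else tuple(d) for d in detections],
        dtype=float,
    ).reshape(-1, 2)
    truth_pts = truth.as_array().astype(float)
    n_det, n_truth = len(det_pts), len(truth_pts)
    if n_det == 0:
        return 0, 0, n_truth
    if n_truth == 0:
        return 0, n_det, 0
    dist = np.sqrt(((det_pts[:, None, :] - truth_pts[None, :, :]) ** 2).sum(-1))
    pairs = [
        (dist[i, j], i, j)
        for i in range(n_det)
        for j in range(n_truth)
        if dist[i, j] <= config.point_tolerance_px
    ]
    pairs.sort()
    used_det: set[int] = set()
    used_truth: set[int] = set()
    tp = 0
    for _, i, j in pairs:
        if config.one_to_one and (i in used_det or j in used_truth):
            continue
        if i in used_det:
            continue
        used_det.add(i)
        used_truth.add(j)
        tp += 1
    return tp, n_det - len(used_det), n_truth - len(used_truth)


def roc_curve(
    detections: Sequence[DetectionRecord],
    truth: PointAnnotationSet,
    total_negatives: int,
    thresholds: Sequence[float],
    config: MatchingConfig,
) -> list[CurvePoint]:
    """Per-threshold sensitivity vs FP/total-negative-pixels, sorted by
    descending threshold."""
    if total_negatives <= 0:
        raise ValueError("total_negatives must be positive")
    points = []
    for thr in sorted(thresholds, reverse=True):
        kept = [d for d in detections if d.score >= thr]
        tp, fp, fn = match_points(kept, truth, config)
        points.append(CurvePoint(threshold=thr, tp=tp, fp=fp, fn=fn, tn=total_negatives - fp))
    return points


def pr_curve(
    detections: Sequence[DetectionRecord],
    truth: PointAnnotationSet,
    thresholds: Sequence[float],
    config: MatchingConfig,
) -> list[CurvePoint]:
    """Precision-recall curve; thresholds that keep zero detections (the
    undefined-precision point) are omitted."""
    points = []
    for thr in sorted(thresholds, reverse=True):
        kept = [d for d in detections if d.score >= thr]
        if not kept:
            continue
        tp, fp, fn = match_points(kept, truth, config)
        points.append(CurvePoint(threshold=thr, tp=tp, fp=fp, fn=fn))
    return points


def froc_curve(
    cluster_detections: Sequence[Sequence[ClusterDetection]],
    cluster_annotations: Sequence[ClusterAnnotationSet],
    thresholds: Sequence[float],
) -> list[tuple[float, float, float]]:
    """FROC over a set of images: for each threshold returns
    ``(threshold, fp_per_image, sensitivity)``.

    A detected cluster is a true positive when its center lies inside an
    annotated region of its image; each annotated region counts as detected
    at most once.  Images without annotations contribute only false
    positives.
    """
    n_images = len(cluster_detections)
    if n_images == 0 or n_images != len(cluster_annotations):
        raise ValueError("need one annotation set per image")
    total_annotated = sum(len(a) for a in cluster_annotations)
    if total_annotated == 0:
        raise ValueError("no annotated clusters; FROC sensitivity undefined")
    out = []
    for thr in sorted(thresholds, reverse=True):
        tp_regions = 0
        fp = 0
        for dets, anns in zip(cluster_detections, cluster_annotations):
            kept = [d for d in dets if d.score >= thr]
            matched_regions = [False] * len(anns)
            for det in kept:
                hit = False
                for k, box in enumerate(anns.boxes()):
                    if box[0] <= det.center[0] <= box[2] and box[1] <= det.center[1] <= box[3]:
                        hit = True
                        if not matched_regions[k]:
                            matched_regions[k] = True
                        break
                if not hit:
                    fp += 1
            tp_regions += sum(matched_regions)
        out.append((thr, fp / n_images, tp_regions / total_annotated))
    return out


def auc(
    xs: Sequence[float], ys: Sequence[float], x_max: float | None = None
) -> float:
    """Trapezoidal area under (xs, ys) after sorting by x, clipped to
    [0, x_max] and normalized by x_max (so the result is in [0, 1] for
    curves bounded by 1 in y)."""
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if len(xs) < 2:
        raise ValueError("need at least two curve points")
    order = np.argsort(xs)
    xs, ys = xs[order], ys[order]
    if x_max is None:
        x_max = float(xs.max())
    if x_max <= 0:
        raise ValueError("x_max must be positive")
    keep = xs <= x_max
    xs, ys = xs[keep], ys[keep]
    return float(np.trapezoid(ys, xs) / x_max)


def score_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Threshold-free ROC AUC of a score against binary labels via the
    rank-sum (Mann-Whitney) statistic, with ties handled by mid-ranks."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need both classes for an AUC")
    ranks = rankdata(scores)
    return float((ranks[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def make_folds(
    image_ids: Sequence[str],
    has_mc: Sequence[bool],
    n_folds: int = 10,
    seed: int = 0,
) -> list[list[str]]:
    """Stratified cross-validation folds over whole images: images with and
    without microcalcifications are each split into ``n_folds`` groups of
    near-uniform size; a fold is the union of one group from each stratum.
    The folds partition the image set (disjoint, union = all)."""
    rng = np.random.default_rng(seed)
    folds: list[list[str]] = [[] for _ in range(n_folds)]
    ids = np.asarray(image_ids)
    flags = np.asarray(has_mc, dtype=bool)
    for stratum in (True, False):
        members = ids[flags == stratum]
        perm = rng.permutation(len(members))
        for k, idx in enumerate(perm):
            folds[k % n_folds].append(str(members[idx]))
    return folds
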