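"""Microcalcification-cluster grouping rules.

Rule 1 (pairwise distance / count): a set of three or more individual
detections whose pairwise distances all stay within ``d_c1`` (default
4 mm) forms a cluster; overlapping candidate sets are resolved greedily by
size, and every emitted cluster must fit inside a square of area ``A_c1``
(default 1 cm^2) centered at its centroid.

Rule 2 (cumulative local probability): the per-pixel sum of individual
detection probabilities over a square window of area ``A_c2``; thresholding
the resulting map and taking 8-connected components yields clusters.

All physical parameters are in mm and converted through the image spacing
(1 cm spans 100 / 200 / 50 pixels at 0.1 / 0.05 / 0.2 mm per pixel).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .config import ClusterRuleConfig
from .io import ClusterAnnotationSet

_EIGHT = np.ones((3, 3), dtype=bool)


@dataclass
class ClusterDetection:
    center: tuple[int, int]
    bbox: tuple[int, int, int, int]  # row_min, col_min, row_max, col_max
    score: float  # member count (rule 1) or max cumulative probability (rule 2)
    rule: str  # "pairwise" or "cumulative"
    members: list[tuple[int, int]] | None = None
    n_members: int = 0


def mm_to_px(length_mm: float, spacing_mm: float) -> int:
    """Physical length to a pixel count (nearest integer), e.g. for window
    sides."""
    if spacing_mm <= 0:
        raise ValueError("spacing_mm must be positive")
    return int(round(length_mm / spacing_mm))


def clusters_rule1(
    detections: list[tuple[int, int]], config: ClusterRuleConfig
) -> list[ClusterDetection]:
    """Pairwise-distance clustering of individual detections.

    For each detection p the neighborhood N(p) collects every detection
    within ``d_c1_mm`` of p (including p).  N(p) is a candidate cluster if
    it has at least three members whose distances are pairwise within
    ``d_c1_mm`` and it fits inside a centroid-centered square of area
    ``a_c1_mm2``.  Overlapping candidates are resolved greedily: keep the
    largest (ties to the smallest seed coordinate), drop candidates sharing
    any member, repeat.  Emitted clusters are therefore member-disjoint.
    """
    pts = np.asarray(detections, dtype=float).reshape(-1, 2)
    n = len(pts)
    if n == 0:
        return []
    d_px = config.d_c1_mm / config.spacing_mm
    half_side_px = 0.5 * np.sqrt(config.a_c1_mm2) / config.spacing_mm
    dist = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))

    candidates = []  # (size, seed_key, member indices frozenset)
    for i in range(n):
        members = np.flatnonzero(dist[i] <= d_px)
        if len(members) < 3:
            continue
        if dist[np.ix_(members, members)].max() > d_px:
            continue  # chain-shaped neighborhoods are not compact clusters
        centroid = pts[members].mean(axis=0)
        if np.abs(pts[members] - centroid).max() > half_side_px:
            continue  # violates the localized-region constraint A_c1
        candidates.append((len(members), (int(pts[i, 0]), int(pts[i, 1])), frozenset(members)))

    candidates.sort(key=lambda t: (-t[0], t[1]))
    out: list[ClusterDetection] = []
    used: set[int] = set()
    for size, _seed, members in candidates:
        if members & used:
            continue
        used |= members
        idx = sorted(members)
        mpts = pts[idx]
        centroid = mpts.mean(axis=0)
        out.append(
            ClusterDetection(
                center=(int(round(centroid[0])), int(round(centroid[1]))),
                bbox=(
                    int(mpts[:, 0].min()), int(mpts[:, 1].min()),
                    int(mpts[:, 0].max()), int(mpts[:, 1].max()),
                ),
                score=float(size),
                rule="pairwise",
                members=[(int(r), int(c)) for r, c in mpts],
                n_members=size,
            )
        )
    return out


def cumulative_probability_map(prob_map: np.ndarray, window_side_px: int) -> np.ndarray:
    """Box sum of the sparse individual-probability grid over a
    ``window_side_px`` square centered at each pixel (zero-padded at the
    borders), computed with an integral image."""
    if window_side_px < 1 or window_side_px % 2 != 1:
        raise ValueError("window_side_px must be an odd positive integer")
    p = np.asarray(prob_map, dtype=np.float64)
    half = window_side_px // 2
    padded = np.zeros((p.shape[0] + 2 * half + 1, p.shape[1] + 2 * half + 1))
    padded[half + 1 : half + 1 + p.shape[0], half + 1 : half + 1 + p.shape[1]] = p
    ii = padded.cumsum(axis=0).cumsum(axis=1)
    s = window_side_px
    out = (
        ii[s:, s:]
        - ii[:-s, s:]
        - ii[s:, :-s]
        + ii[:-s, :-s]
    )
    return out[: p.shape[0], : p.shape[1]]


def clusters_rule2(
    prob_map: np.ndarray, config: ClusterRuleConfig
) -> list[ClusterDetection]:
    """Threshold the cumulative local probability map and emit one cluster
    per 8-connected component; the bounding box is the union of the member
    pixels' windows (clipped to the image), the center the component
    centroid, the score the component's maximum cumulative probability."""
    if config.p_c_threshold < 0:
        raise ValueError("p_c_threshold must be >= 0")
    side = mm_to_px(np.sqrt(config.a_c2_mm2), config.spacing_mm)
    if side % 2 == 0:
        side += 1  # windows are centered, so force an odd side
    p_c = cumulative_probability_map(prob_map, side)
    above = p_c >= config.p_c_threshold
    labels, n = ndimage.label(above, structure=_EIGHT)
    half = side // 2
    out = []
    for lab in range(1, n + 1):
        coords = np.argwhere(labels == lab)
        centroid = coords.mean(axis=0)
        out.append(
            ClusterDetection(
                center=(int(round(centroid[0])), int(round(centroid[1]))),
                bbox=(
                    max(0, int(coords[:, 0].min()) - half),
                    max(0, int(coords[:, 1].min()) - half),
                    min(prob_map.shape[0] - 1, int(coords[:, 0].max()) + half),
                    min(prob_map.shape[1] - 1, int(coords[:, 1].max()) + half),
                ),
                score=float(p_c[labels == lab].max()),
                rule="cumulative",
                n_members=len(coords),
            )
        )
    return out


def match_cluster(detected: ClusterDetection, annotations: ClusterAnnotationSet) -> bool:
    """True iff the detected cluster's center lies inside any annotated
    region (inclusive boundaries; circles via their tight bounding square)."""
    r, c = detected.center
    for row_min, col_min, row_max, col_max in annotations.boxes():
        if row_min <= r <= row_max and col_min <= c <= col_max:
            return True
    return False


def write_clusters(
    clusters: list[ClusterDetection], path: str | Path, image_id: str = ""
) -> None:
    rows = [
        (
            image_id, cl.rule, cl.center[0], cl.center[1],
            cl.bbox[0], cl.bbox[1], cl.bbox[2], cl.bbox[3],
            f"{cl.score:.12g}", cl.n_members,
        )
        for cl in clusters
    ]
    pd.DataFrame(
        rows,
        columns=[
            "image_id", "rule", "center_row", "center_col",
            "row_min", "col_min", "row_max", "col_max", "score", "n_members",
        ],
    ).to_csv(path, index=False)
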