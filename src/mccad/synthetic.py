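"""Synthetic mammogram-like phantoms with full ground truth.

Microcalcifications appear on mammograms as sub-millimetre bright blobs on
spatially correlated tissue; the phantom emulates exactly the structures the
detector must separate:

* a breast region (half-ellipse against a near-zero "empty space" border),
* low-frequency tissue texture (white noise convolved with a wide Gaussian),
* bright isotropic Gaussian bumps for individual microcalcifications, a
  fraction of them planted in compact clusters,
* bright Gaussian-profile ridges as vessel-like tubular distractors,
* additive pixel noise.

The generator is deterministic given its seed, and its ground truth (point
and cluster annotations, breast mask) drives every downstream test.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .io import ClusterAnnotationSet, MammogramImage, PointAnnotationSet


class PlacementError(RuntimeError):
    """Could not place the requested objects after bounded retries."""


@dataclass
class PhantomSpec:
    """Generation parameters; the defaults are the package's standard study
    conditions (0.2 mm/pixel, ~50 microcalcifications per 512x512 image,
    60% of them in clusters of radius 2 mm)."""

    image_shape: tuple[int, int] = (512, 512)
    spacing_mm: float = 0.2
    breast_mask_shape: str = "half-ellipse"  # or "full"
    base_level: float = 30.0
    tissue_amp: float = 10.0
    tissue_corr_len_px: float = 8.0
    mc_count: int = 50
    mc_amplitude_range: tuple[float, float] = (25.0, 60.0)
    mc_sigma_px_range: tuple[float, float] = (0.8, 1.6)
    cluster_fraction: float = 0.6
    cluster_radius_mm: float = 2.0
    cluster_min_size: int = 3
    scatter_min_sep_mm: float = 4.0
    ridge_count: int = 3
    ridge_amp: float = 15.0
    ridge_sigma_px: float = 2.0
    noise_sd: float = 2.0
    bit_depth: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mc_count < 0 or self.ridge_count < 0:
            raise ValueError("object counts must be non-negative")
        if not (0.0 <= self.cluster_fraction <= 1.0):
            raise ValueError("cluster_fraction must be in [0, 1]")
        if self.cluster_min_size < 3:
            raise ValueError("cluster_min_size must be >= 3")
        for lo, hi in (self.mc_amplitude_range, self.mc_sigma_px_range):
            if hi < lo:
                raise ValueError("ranges must be non-empty (hi >= lo)")
        if self.mc_sigma_px_range[0] <= 0:
            raise ValueError("mc sigma range must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.breast_mask_shape not in ("half-ellipse", "full"):
            raise ValueError(f"unknown breast_mask_shape {self.breast_mask_shape!r}")


@dataclass
class Phantom:
    """A generated image plus its complete ground truth."""

    image: MammogramImage
    mc_points: PointAnnotationSet
    clusters: ClusterAnnotationSet
    breast_mask: np.ndarray
    spec: PhantomSpec | None = None


def ideal_blob_image(
    shape: tuple[int, int],
    center: tuple[float, float],
    amplitude: float,
    sigma_px: float,
    spacing_mm: float = 0.1,
    bit_depth: int = 16,
) -> MammogramImage:
    """Analytic isotropic Gaussian bump on a zero background (no clipping):
    ``I(p) = amplitude * exp(-|p - center|^2 / (2 sigma^2))``.

    Serves as the closed-form input for checking Hessian responses.
    """
    if sigma_px <= 0:
        raise ValueError("sigma_px must be positive")
    rr, cc = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    d2 = (rr - center[0]) ** 2 + (cc - center[1]) ** 2
    pixels = amplitude * np.exp(-d2 / (2.0 * sigma_px**2))
    return MammogramImage(pixels=pixels, spacing_mm=spacing_mm, bit_depth=bit_depth)


def breast_mask_for(spec: PhantomSpec) -> np.ndarray:
    """The phantom's breast support: a half-ellipse attached to the left
    image edge (chest wall), or the full frame."""
    rows, cols = spec.image_shape
    if spec.breast_mask_shape == "full":
        return np.ones((rows, cols), dtype=bool)
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    a = 0.48 * rows  # semi-axis along rows
    b = 0.85 * cols  # semi-axis along cols, anchored at col 0
    return ((rr - rows / 2.0) / a) ** 2 + (cc / b) ** 2 <= 1.0


def _tissue_background(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    noise = rng.standard_normal(spec.image_shape)
    smooth = ndimage.gaussian_filter(noise, spec.tissue_corr_len_px, mode="reflect")
    sd = smooth.std()
    if sd > 0:
        smooth = smooth / sd
    return spec.base_level + spec.tissue_amp * smooth


def _add_bump(img: np.ndarray, center: tuple[float, float], amp: float, sigma: float) -> None:
    r0, c0 = center
    rad = int(np.ceil(5 * sigma))
    rlo, rhi = max(0, int(r0) - rad), min(img.shape[0], int(r0) + rad + 1)
    clo, chi = max(0, int(c0) - rad), min(img.shape[1], int(c0) + rad + 1)
    rr, cc = np.meshgrid(np.arange(rlo, rhi), np.arange(clo, chi), indexing="ij")
    img[rlo:rhi, clo:chi] += amp * np.exp(
        -((rr - r0) ** 2 + (cc - c0) ** 2) / (2.0 * sigma**2)
    )


def _add_ridge(img: np.ndarray, mask: np.ndarray, p0, p1, amp: float, sigma: float) -> None:
    """Gaussian-profile line segment from p0 to p1, restricted to the mask."""
    rr, cc = np.meshgrid(np.arange(img.shape[0]), np.arange(img.shape[1]), indexing="ij")
    d = np.stack([rr - p0[0], cc - p0[1]], axis=-1).astype(float)
    v = np.asarray([p1[0] - p0[0], p1[1] - p0[1]], dtype=float)
    vv = v @ v
    t = np.clip((d @ v) / vv, 0.0, 1.0) if vv > 0 else np.zeros_like(rr, dtype=float)
    perp2 = (d[..., 0] - t * v[0]) ** 2 + (d[..., 1] - t * v[1]) ** 2
    img += np.where(mask, amp * np.exp(-perp2 / (2.0 * sigma**2)), 0.0)


def _interior_points(mask: np.ndarray, margin_px: float) -> np.ndarray:
    """(N, 2) array of mask pixels at least margin_px from the mask border."""
    eroded = ndimage.binary_erosion(
        mask, structure=np.ones((3, 3), dtype=bool), iterations=max(1, int(np.ceil(margin_px)))
    )
    return np.argwhere(eroded)


def _partition_cluster_sizes(n: int, min_size: int, rng: np.random.Generator) -> list[int]:
    """Split n points into cluster sizes, each >= min_size."""
    sizes: list[int] = []
    remaining = n
    while remaining >= min_size:
        hi = min(remaining, min_size + 4)
        size = int(rng.integers(min_size, hi + 1))
        if remaining - size < min_size and remaining - size > 0:
            size = remaining  # absorb a too-small remainder
        sizes.append(size)
        remaining -= size
    if remaining > 0 and sizes:
        sizes[-1] += remaining
    return sizes


_MAX_TRIES = 2000


def generate_phantom(spec: PhantomSpec) -> Phantom:
    """Render a phantom per the spec; deterministic given ``spec.seed``.

    A fraction ``cluster_fraction`` of the microcalcifications is grouped in
    clusters: members lie within ``cluster_radius_mm`` of the cluster center
    (so pairwise member distances stay below twice that radius) and at least
    ``3 * max(mc_sigma_px_range)`` pixels apart, keeping the blobs
    resolvable as distinct objects.  The remainder is scattered uniformly
    with the same minimum separation from any other microcalcification and,
    additionally, at least ``scatter_min_sep_mm`` beyond any cluster's
    radius: scattered points are isolated deposits by construction, so the
    annotated clusters are the *only* groupings that satisfy a
    pairwise-distance rule with threshold up to ``scatter_min_sep_mm``.
    Cluster centers are kept ``2 * cluster_radius + scatter_min_sep`` apart
    so no cross-cluster point pair falls within that threshold either.
    """
    rng = np.random.default_rng(spec.seed)
    mask = breast_mask_for(spec)
    img = np.where(mask, _tissue_background(spec, rng), 0.0)
    # faint non-breast border: empty space is dark but not perfectly black
    img += np.where(mask, 0.0, 1.0)

    cluster_radius_px = spec.cluster_radius_mm / spec.spacing_mm
    min_sep_px = 3.0 * spec.mc_sigma_px_range[1]

    n_clustered = int(round(spec.cluster_fraction * spec.mc_count))
    sizes = _partition_cluster_sizes(n_clustered, spec.cluster_min_size, rng)
    n_scattered = spec.mc_count - sum(sizes)

    interior = _interior_points(mask, cluster_radius_px + 4)
    if spec.mc_count > 0 and len(interior) == 0:
        raise PlacementError("breast mask too small for requested objects")

    placed: list[tuple[float, float]] = []
    cluster_regions: list[dict] = []

    scatter_sep_px = spec.scatter_min_sep_mm / spec.spacing_mm
    # centers far enough apart that no cross-cluster point pair can fall
    # within scatter_sep_px of each other
    center_sep_px = 2.0 * cluster_radius_px + scatter_sep_px
    centers: list[tuple[float, float]] = []
    for _ in sizes:
        for _try in range(_MAX_TRIES):
            r, c = interior[rng.integers(len(interior))]
            if all(np.hypot(r - rc, c - cc0) > center_sep_px for rc, cc0 in centers):
                centers.append((float(r), float(c)))
                break
        else:
            raise PlacementError("could not place cluster centers")

    for size, (rc, cc0) in zip(sizes, centers):
        members: list[tuple[float, float]] = []
        for _ in range(size):
            for _try in range(_MAX_TRIES):
                rho = cluster_radius_px * np.sqrt(rng.uniform())
                ang = rng.uniform(0, 2 * np.pi)
                p = (rc + rho * np.cos(ang), cc0 + rho * np.sin(ang))
                pi = (int(round(p[0])), int(round(p[1])))
                if not (0 <= pi[0] < mask.shape[0] and 0 <= pi[1] < mask.shape[1]):
                    continue
                if not mask[pi]:
                    continue
                if all(np.hypot(p[0] - q[0], p[1] - q[1]) >= min_sep_px for q in members):
                    members.append(p)
                    break
            else:
                raise PlacementError("could not place cluster member")
        placed.extend(members)
        cluster_regions.append(
            ClusterAnnotationSet.circle(rc, cc0, cluster_radius_px)
        )

    scatter_interior = _interior_points(mask, 4)
    for _ in range(n_scattered):
        for _try in range(_MAX_TRIES):
            r, c = scatter_interior[rng.integers(len(scatter_interior))]
            p = (float(r), float(c))
            if not all(
                np.hypot(p[0] - rc, p[1] - cc0) > cluster_radius_px + scatter_sep_px
                for rc, cc0 in centers
            ):
                continue  # scattered points never approach a planted cluster
            if all(
                np.hypot(p[0] - q[0], p[1] - q[1]) >= max(min_sep_px, scatter_sep_px + 2)
                for q in placed
            ):
                placed.append(p)
                break
        else:
            raise PlacementError("could not place scattered microcalcification")

    point_coords = []
    seen = set()
    for p in placed:
        amp = rng.uniform(*spec.mc_amplitude_range)
        sig = rng.uniform(*spec.mc_sigma_px_range)
        _add_bump(img, p, amp, sig)
        pi = (int(round(p[0])), int(round(p[1])))
        if pi in seen:  # rounding collision: extremely rare, but the
            raise PlacementError("duplicate rounded coordinates")  # set must stay unique
        seen.add(pi)
        point_coords.append(pi)

    border = np.argwhere(ndimage.binary_dilation(mask) & ~mask)
    inner = _interior_points(mask, 10)
    for _ in range(spec.ridge_count):
        if len(border) == 0 or len(inner) == 0:
            break
        p0 = border[rng.integers(len(border))]
        p1 = inner[rng.integers(len(inner))]
        _add_ridge(img, mask, p0, p1, spec.ridge_amp, spec.ridge_sigma_px)

    if spec.noise_sd > 0:
        img += np.where(mask, rng.normal(0.0, spec.noise_sd, size=img.shape), 0.0)

    img = np.clip(np.round(img), 0, 2**spec.bit_depth - 1)
    image = MammogramImage(pixels=img, spacing_mm=spec.spacing_mm, bit_depth=spec.bit_depth)
    image_id = f"phantom-{spec.seed}"
    return Phantom(
        image=image,
        mc_points=PointAnnotationSet(points=point_coords, image_id=image_id),
        clusters=ClusterAnnotationSet(regions=cluster_regions, image_id=image_id),
        breast_mask=mask,
        spec=spec,
    )
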