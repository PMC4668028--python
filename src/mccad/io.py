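"""Image / annotation / detection I/O with physical pixel-spacing metadata.

All coordinates throughout the package are 0-based ``(row, col)`` with row 0
at the top of the image.  Pixel spacing is isotropic and given in mm/pixel;
it is supplied explicitly (or via a sidecar config), never inferred from the
raster file, because PGM carries no spacing field and the supported datasets
differ (0.05 / 0.1 / 0.2 mm).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd


class FormatError(ValueError):
    """Unreadable or unsupported raster content (e.g. a color image)."""


@dataclass
class MammogramImage:
    """A 2-D grayscale mammogram with physical metadata.

    Parameters
    ----------
    pixels : ndarray
        Non-negative intensity grid, row-major; row index runs down (y),
        column index runs right (x).
    spacing_mm : float
        Physical size of one (square) pixel in millimetres.
    bit_depth : int
        Sample depth; intensities must lie in ``[0, 2**bit_depth - 1]``.
    """

    pixels: np.ndarray
    spacing_mm: float
    bit_depth: int = 8

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise FormatError(f"expected a 2-D grid, got shape {self.pixels.shape}")
        if self.pixels.shape[0] < 3 or self.pixels.shape[1] < 3:
            raise ValueError("image must be at least 3x3 pixels")
        if self.bit_depth not in (8, 12, 16):
            raise ValueError(f"bit_depth must be 8, 12 or 16, got {self.bit_depth}")
        if not self.spacing_mm > 0:
            raise ValueError("spacing_mm must be positive")
        if self.pixels.min() < 0 or self.pixels.max() > self.max_intensity:
            raise ValueError(
                f"intensities must lie in [0, {self.max_intensity}] for "
                f"bit depth {self.bit_depth}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    @property
    def max_intensity(self) -> int:
        return 2**self.bit_depth - 1

    def mm_to_px(self, length_mm: float) -> float:
        return length_mm / self.spacing_mm


@dataclass
class PointAnnotationSet:
    """Ground-truth individual-microcalcification pixel coordinates."""

    points: list[tuple[int, int]]
    image_id: str = ""

    def __post_init__(self) -> None:
        pts = [(int(r), int(c)) for r, c in self.points]
        if len(set(pts)) != len(pts):
            raise ValueError("duplicate point annotations")
        self.points = pts

    def __len__(self) -> int:
        return len(self.points)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.points, dtype=np.int64).reshape(-1, 2)

    def validate_bounds(self, shape: tuple[int, int]) -> None:
        for r, c in self.points:
            if not (0 <= r < shape[0] and 0 <= c < shape[1]):
                raise ValueError(f"point ({r}, {c}) outside image of shape {shape}")


@dataclass
class ClusterAnnotationSet:
    """Ground-truth cluster regions, as boxes or circles.

    Circles are stored as given but converted to their tight bounding square
    for containment tests (``boxes()``), which unifies the two annotation
    dialects found in practice (center+radius circles vs corner boxes).
    """

    regions: list[dict]
    image_id: str = ""

    def __post_init__(self) -> None:
        for reg in self.regions:
            if reg["shape"] == "box":
                if not (reg["row_max"] > reg["row_min"] and reg["col_max"] > reg["col_min"]):
                    raise ValueError(f"degenerate box annotation: {reg}")
            elif reg["shape"] == "circle":
                if not reg["radius_px"] > 0:
                    raise ValueError(f"non-positive circle radius: {reg}")
            else:
                raise ValueError(f"unknown region shape {reg['shape']!r}")

    def __len__(self) -> int:
        return len(self.regions)

    def boxes(self) -> list[tuple[float, float, float, float]]:
        """Regions as (row_min, col_min, row_max, col_max); circles become
        their tight enclosing square."""
        out = []
        for reg in self.regions:
            if reg["shape"] == "box":
                out.append((reg["row_min"], reg["col_min"], reg["row_max"], reg["col_max"]))
            else:
                r, c, rad = reg["row_c"], reg["col_c"], reg["radius_px"]
                out.append((r - rad, c - rad, r + rad, c + rad))
        return out

    @staticmethod
    def box(row_min: float, col_min: float, row_max: float, col_max: float) -> dict:
        return {
            "shape": "box",
            "row_min": float(row_min),
            "col_min": float(col_min),
            "row_max": float(row_max),
            "col_max": float(col_max),
        }

    @staticmethod
    def circle(row_c: float, col_c: float, radius_px: float) -> dict:
        return {
            "shape": "circle",
            "row_c": float(row_c),
            "col_c": float(col_c),
            "radius_px": float(radius_px),
        }


@dataclass(frozen=True)
class DetectionRecord:
    """A single individual-microcalcification detection."""

    point: tuple[int, int]
    score: float
    stage: str = "drbm"  # "rf" or "drbm"
    image_id: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"score must be in [0, 1], got {self.score}")
        if self.stage not in ("rf", "drbm"):
            raise ValueError(f"stage must be 'rf' or 'drbm', got {self.stage!r}")


# ---------------------------------------------------------------------------
# images


def read_image(path: str | Path, spacing_mm: float, bit_depth: int | None = None) -> MammogramImage:
    """Read a grayscale PGM/PNG/TIFF raster into a :class:`MammogramImage`.

    ``bit_depth`` is inferred from the file's sample dtype (uint8 -> 8,
    uint16 -> 16) unless given explicitly (e.g. 12-bit data stored in a
    16-bit container).
    """
    path = Path(path)
    try:
        arr = iio.imread(path)
    except Exception as exc:  # noqa: BLE001 - plugin exceptions vary
        raise FormatError(f"cannot read image {path}: {exc}") from exc
    if arr.ndim == 3:
        raise FormatError(f"{path} is not grayscale (shape {arr.shape})")
    if bit_depth is None:
        if arr.dtype == np.uint8:
            bit_depth = 8
        elif arr.dtype == np.uint16:
            bit_depth = 16
        else:
            raise FormatError(f"unsupported sample dtype {arr.dtype} in {path}")
    return MammogramImage(pixels=arr, spacing_mm=spacing_mm, bit_depth=bit_depth)


def write_image(image: MammogramImage, path: str | Path) -> None:
    """Write the image to PGM/PNG/TIFF, chosen by extension; bit depths above
    8 are stored in a 16-bit container."""
    path = Path(path)
    dtype = np.uint8 if image.bit_depth == 8 else np.uint16
    arr = np.round(image.pixels).astype(dtype)
    iio.imwrite(path, arr)


# ---------------------------------------------------------------------------
# annotations

_POINT_COLUMNS = ["image_id", "row", "col"]
_CLUSTER_COLUMNS = ["image_id", "shape", "row_a", "col_a", "row_b", "col_b"]
_DETECTION_COLUMNS = ["image_id", "row", "col", "score", "stage"]


def read_point_annotations(path: str | Path) -> PointAnnotationSet:
    df = pd.read_csv(path)
    if list(df.columns) != _POINT_COLUMNS:
        raise ValueError(f"expected columns {_POINT_COLUMNS}, got {list(df.columns)}")
    image_id = str(df["image_id"].iloc[0]) if len(df) else ""
    points = list(zip(df["row"].astype(int), df["col"].astype(int)))
    return PointAnnotationSet(points=points, image_id=image_id)


def write_point_annotations(annotations: PointAnnotationSet, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "image_id": [annotations.image_id] * len(annotations),
            "row": [p[0] for p in annotations.points],
            "col": [p[1] for p in annotations.points],
        },
        columns=_POINT_COLUMNS,
    )
    df.to_csv(path, index=False)


def read_cluster_annotations(path: str | Path) -> ClusterAnnotationSet:
    df = pd.read_csv(path)
    if list(df.columns) != _CLUSTER_COLUMNS:
        raise ValueError(f"expected columns {_CLUSTER_COLUMNS}, got {list(df.columns)}")
    regions = []
    image_id = str(df["image_id"].iloc[0]) if len(df) else ""
    for _, row in df.iterrows():
        if row["shape"] == "box":
            regions.append(
                ClusterAnnotationSet.box(row["row_a"], row["col_a"], row["row_b"], row["col_b"])
            )
        elif row["shape"] == "circle":
            regions.append(ClusterAnnotationSet.circle(row["row_a"], row["col_a"], row["row_b"]))
        else:
            raise ValueError(f"unknown shape {row['shape']!r}")
    return ClusterAnnotationSet(regions=regions, image_id=image_id)


def write_cluster_annotations(annotations: ClusterAnnotationSet, path: str | Path) -> None:
    rows = []
    for reg in annotations.regions:
        if reg["shape"] == "box":
            rows.append(
                (annotations.image_id, "box", reg["row_min"], reg["col_min"],
                 reg["row_max"], reg["col_max"])
            )
        else:
            rows.append(
                (annotations.image_id, "circle", reg["row_c"], reg["col_c"],
                 reg["radius_px"], "")
            )
    pd.DataFrame(rows, columns=_CLUSTER_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# detections


def write_detections(records: Sequence[DetectionRecord], path: str | Path) -> None:
    """Write detections as CSV; scores keep >= 9 significant digits so a
    read-back reproduces them within 1e-9."""
    rows = [
        (rec.image_id, rec.point[0], rec.point[1], f"{rec.score:.12g}", rec.stage)
        for rec in records
    ]
    pd.DataFrame(rows, columns=_DETECTION_COLUMNS).to_csv(path, index=False)


def read_detections(path: str | Path) -> list[DetectionRecord]:
    df = pd.read_csv(path)
    if list(df.columns) != _DETECTION_COLUMNS:
        raise ValueError(f"expected columns {_DETECTION_COLUMNS}, got {list(df.columns)}")
    return [
        DetectionRecord(
            point=(int(row["row"]), int(row["col"])),
            score=float(row["score"]),
            stage=str(row["stage"]),
            image_id="" if pd.isna(row["image_id"]) else str(row["image_id"]),
        )
        for _, row in df.iterrows()
    ]
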