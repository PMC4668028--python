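"""Configuration objects, dataset presets, and YAML loading.

Three named presets mirror the standard acquisition profiles the detector
is tuned for (digital 0.1 mm/px, film 0.05 mm/px, downsampled film
0.2 mm/px): RF scale sets, RF probability thresholds, DRBM patch sides,
hidden-layer sizes, learning rates and epoch counts.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml


@dataclass
class ForestConfig:
    n_trees: int = 100
    max_depth: int = 30
    min_node_fraction: float = 0.01
    n_candidate_splits: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.max_depth < 0:
            raise ValueError("max_depth must be >= 0")
        if not 0.0 < self.min_node_fraction < 1.0:
            raise ValueError("min_node_fraction must be in (0, 1)")


@dataclass
class PipelineConfig:
    scales: tuple[float, ...] = (1.0,)
    theta_rf: float = 0.3
    theta_drbm: float = 0.5
    patch_side: int = 15
    nms_sigma_px: float | None = None  # default: middle element of scales
    spacing_mm: float = 0.1
    seg_n_bins: int = 64
    seg_n_examine: int = 8
    seg_dilate_radius_px: int = 5

    def __post_init__(self) -> None:
        self.scales = tuple(float(s) for s in self.scales)
        if not self.scales or any(s <= 0 for s in self.scales):
            raise ValueError("scales must be positive")
        if any(b <= a for a, b in zip(self.scales, self.scales[1:])):
            raise ValueError("scales must be strictly increasing")
        for name in ("theta_rf", "theta_drbm"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.patch_side % 2 != 1:
            raise ValueError("patch_side must be odd")
        if self.spacing_mm <= 0:
            raise ValueError("spacing_mm must be positive")

    @property
    def nms_sigma(self) -> float:
        if self.nms_sigma_px is not None:
            return self.nms_sigma_px
        return self.scales[len(self.scales) // 2]


@dataclass
class ClusterRuleConfig:
    d_c1_mm: float = 4.0
    a_c1_mm2: float = 100.0
    a_c2_mm2: float = 100.0
    p_c_threshold: float = 1.0
    spacing_mm: float = 0.1

    def __post_init__(self) -> None:
        for name in ("d_c1_mm", "a_c1_mm2", "a_c2_mm2", "spacing_mm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.p_c_threshold < 0:
            raise ValueError("p_c_threshold must be >= 0")


@dataclass
class DRBMPreset:
    n_hidden: int
    learning_rate: float
    n_epochs: int


@dataclass
class Preset:
    pipeline: PipelineConfig
    drbm: DRBMPreset
    forest: ForestConfig = field(default_factory=ForestConfig)


PRESETS: dict[str, Preset] = {
    # full-resolution digital mammography, 0.1 mm/px, 12-bit
    "snubh": Preset(
        pipeline=PipelineConfig(
            scales=(1.0,), theta_rf=0.3, patch_side=15, spacing_mm=0.1
        ),
        drbm=DRBMPreset(n_hidden=50, learning_rate=0.02, n_epochs=100),
    ),
    # digitized film, 0.05 mm/px, 8-bit
    "mias": Preset(
        pipeline=PipelineConfig(
            scales=(1.0, 2.0, 3.0, 4.0, 5.0), theta_rf=0.5, patch_side=29,
            spacing_mm=0.05,
        ),
        drbm=DRBMPreset(n_hidden=200, learning_rate=0.02, n_epochs=30),
    ),
    # downsampled film, 0.2 mm/px, 8-bit
    "mini_mias": Preset(
        pipeline=PipelineConfig(
            scales=(0.5, 1.0, 1.5, 2.0, 2.5), theta_rf=0.5, patch_side=9,
            spacing_mm=0.2,
        ),
        drbm=DRBMPreset(n_hidden=200, learning_rate=0.04, n_epochs=30),
    ),
}


def _build(cls, data: dict, name: str):
    allowed = {f.name for f in fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"unknown key(s) in {name!r} section: {sorted(unknown)}")
    return cls(**data)


def load_config(path: str | Path) -> dict:
    """Load a YAML run config.

    Top-level keys: optional ``preset`` (one of ``snubh``, ``mias``,
    ``mini_mias``) plus optional ``pipeline``, ``forest``, ``cluster``,
    ``drbm`` sections overriding preset fields.  Unknown keys are rejected
    and all invariants are validated on construction.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known_top = {"preset", "pipeline", "forest", "cluster", "drbm"}
    unknown = set(raw) - known_top
    if unknown:
        raise ValueError(f"unknown top-level key(s): {sorted(unknown)}")
    preset_name = raw.get("preset")
    if preset_name is not None:
        if preset_name not in PRESETS:
            raise ValueError(f"unknown preset {preset_name!r}")
        preset = PRESETS[preset_name]
        pipe = asdict(preset.pipeline)
        forest = asdict(preset.forest)
        drbm = asdict(preset.drbm)
    else:
        pipe, forest, drbm = asdict(PipelineConfig()), asdict(ForestConfig()), asdict(
            DRBMPreset(n_hidden=50, learning_rate=0.02, n_epochs=100)
        )
    pipe.update(raw.get("pipeline", {}))
    forest.update(raw.get("forest", {}))
    drbm.update(raw.get("drbm", {}))
    cluster = {"spacing_mm": pipe["spacing_mm"]}
    cluster.update(raw.get("cluster", {}))
    return {
        "pipeline": _build(PipelineConfig, pipe, "pipeline"),
        "forest": _build(ForestConfig, forest, "forest"),
        "drbm": _build(DRBMPreset, drbm, "drbm"),
        "cluster": _build(ClusterRuleConfig, cluster, "cluster"),
    }
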