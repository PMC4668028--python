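"""Shared fixtures: small phantoms and a quickly trained cascade.

The tiny cascade (one Hessian scale, 8 trees, 16 hidden units, 256x256
phantoms) exists so pipeline/CLI tests exercise real trained models without
paying for the full study; the full-scale end-to-end run lives in
test_acceptance.py.
"""

from __future__ import annotations

import pytest

from mccad.config import DRBMPreset, ForestConfig, PipelineConfig
from mccad.synthetic import PhantomSpec, generate_phantom
from mccad.training import train_cascade

TINY_PIPELINE = PipelineConfig(
    scales=(1.0,), theta_rf=0.5, theta_drbm=0.5, patch_side=9, spacing_mm=0.2
)


def tiny_spec(seed: int) -> PhantomSpec:
    return PhantomSpec(image_shape=(256, 256), mc_count=12, seed=seed)


@pytest.fixture(scope="session")
def tiny_phantoms():
    return [generate_phantom(tiny_spec(s)) for s in (11, 12)]


@pytest.fixture(scope="session")
def tiny_cascade(tiny_phantoms):
    forest, model, cfg = train_cascade(
        tiny_phantoms,
        TINY_PIPELINE,
        ForestConfig(n_trees=8),
        DRBMPreset(n_hidden=16, learning_rate=0.5, n_epochs=60),
        seed=3,
        drbm_method="disc",
    )
    return forest, model, cfg
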