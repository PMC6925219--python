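"""Shared fixtures: canonical noise-free phantoms used across test modules."""

import numpy as np
import pytest

from gliavasc import (
    AnalysisConfig,
    CellSpec,
    SceneConfig,
    generate_scene,
    z_project_max,
)

PX = 0.25  # um/px used by all fixtures


@pytest.fixture(scope="session")
def config():
    return AnalysisConfig()


@pytest.fixture(scope="session")
def canonical_scene():
    """Noise-free scene: one vessel, four cells at gaps 0/0.5/2/5 um."""
    cfg = SceneConfig(seed=0,
                      cells=CellSpec(count=4, gaps_um=(0.0, 0.5, 2.0, 5.0)))
    stack, truth = generate_scene(cfg)
    return cfg, stack, truth


@pytest.fixture(scope="session")
def canonical_channels(canonical_scene):
    """Projected channels of the canonical scene, keyed by label."""
    _cfg, stack, _truth = canonical_scene
    proj = z_project_max(stack)
    return dict(zip(stack.channel_labels, proj))


def leak_scene(fraction_10kda, seed=0, noise=None, field=256):
    """Cell-free two-dextran scene used by the leakage tests."""
    from gliavasc import NoiseSpec

    cfg = SceneConfig(
        field_size_px=(field, field), seed=seed,
        cells=CellSpec(count=0),
        leak_fraction_per_channel={10: fraction_10kda, 70: 0.0},
        noise=noise or NoiseSpec(),
    )
    return generate_scene(cfg)


def match_truth_cell(detected, truth):
    """Ground-truth cell record nearest a detected cell's centroid."""
    d = [abs(detected.centroid[0] - c.center_zyx_px[1])
         + abs(detected.centroid[1] - c.center_zyx_px[2])
         for c in truth.cells]
    return truth.cells[int(np.argmin(d))]
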