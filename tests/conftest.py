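from __future__ import annotations

import numpy as np
import pytest

from crownedge import (
    SceneSpec,
    generate_label_map,
    make_scene,
    render_cube,
    render_guidance,
    sample_points,
)


@pytest.fixture(scope="session")
def small_spec() -> SceneSpec:
    """A small but fully structured scene: 4 classes, 12 bands."""
    return SceneSpec(height=64, width=64, n_bands=12, region_smoothness=6.0, seed=7)


@pytest.fixture(scope="session")
def small_scene(small_spec):
    labels = generate_label_map(small_spec)
    cube = render_cube(labels, small_spec)
    guidance = render_guidance(labels, small_spec)
    return labels, cube, guidance


@pytest.fixture(scope="session")
def small_samples(small_scene):
    labels, _, _ = small_scene
    return sample_points(labels, n_per_class=120, seed=7)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
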