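import numpy as np
import pytest

from pointseg.core import CentroidSet
from pointseg.network import ModelConfig
from pointseg.synthetic import SceneConfig, generate_scene


@pytest.fixture(scope="session")
def small_scene_config():
    return SceneConfig(
        height=64,
        width=64,
        n_nuclei=8,
        radius_range=(4, 7),
        elongation_prob=0.3,
        touching_pairs=1,
        point_jitter_sd=1.0,
        seed=1,
    )


@pytest.fixture(scope="session")
def small_scene(small_scene_config):
    return generate_scene(small_scene_config)


@pytest.fixture(scope="session")
def tiny_model_config():
    return ModelConfig(n_gauss_branches=2, backbone="tiny", patch_grid=4, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def five_points():
    return CentroidSet.from_points([(10, 12), (40, 8), (25, 50), (55, 55), (5, 60)])
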