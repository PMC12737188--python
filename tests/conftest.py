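import numpy as np
import pytest

from holoquant.synthetic import SceneConfig, generate_scene
from holoquant.volume_io import VoxelSpacing


def tiny_scene_config(**overrides) -> SceneConfig:
    """A small, fast scene: 2 cells, modest aggregate load, no noise."""
    defaults = dict(
        shape=(32, 96, 96),
        spacing=VoxelSpacing(0.5, 0.25, 0.25),
        n_cells=2,
        cell_radius_um=(4.0, 0.3),
        aggregates_per_cell=(15.0, 4.0),
        droplets_per_cell=0.0,
        noise_sd_ri=0.0,
        uptake_association=0.35,
        seed=11,
    )
    defaults.update(overrides)
    return SceneConfig(**defaults)


@pytest.fixture(scope="session")
def tiny_scene():
    """One noise-free scene reused by read-only tests."""
    cfg = tiny_scene_config()
    tomo, fluor, truth = generate_scene(cfg)
    return cfg, tomo, fluor, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
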