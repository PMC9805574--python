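import numpy as np
import pytest

from fluoro4d.io5d import View, Volume4D
from fluoro4d.phantom import PhantomConfig, make_dataset, render_channel, sample_geometry


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_volume(rng):
    return Volume4D(rng.uniform(0, 1, size=(12, 10, 5, 4)).astype(np.float32), View.XYZ_T)


@pytest.fixture(scope="session")
def phantom_cfg():
    """Noise-free mid-size phantom shared across quantification tests."""
    return PhantomConfig(grid=(96, 96, 6, 6), n_cells=16, noise=(0.0, 0.0), seed=7)


@pytest.fixture(scope="session")
def phantom_geom(phantom_cfg):
    return sample_geometry(phantom_cfg)


@pytest.fixture(scope="session")
def phantom_channels(phantom_cfg, phantom_geom):
    return {
        kind: render_channel(phantom_geom, kind, phantom_cfg)
        for kind in ("ecad", "myo", "jub")
    }


@pytest.fixture(scope="session")
def tiny_training_set():
    """8 noisy 32x32x8x4 myo->ecad pairs, the desk-scale training conditions."""
    cfg = PhantomConfig(grid=(32, 32, 8, 4), n_cells=9, seed=42)
    pairs, geoms = make_dataset(cfg, 8, "myo", "ecad")
    return cfg, pairs, geoms
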