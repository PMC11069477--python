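import numpy as np
import pytest

import polartissue as pt


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


def random_physical_stokes(rng, n):
    """Random physical Stokes vectors with s0 = 1: polarized part drawn
    uniformly inside the unit ball."""
    v = rng.standard_normal((n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    radius = rng.uniform(0, 1, n) ** (1 / 3)
    pol = v * radius[:, None]
    return np.column_stack([np.ones(n), pol])


@pytest.fixture(scope="session")
def small_noiseless_dataset():
    """1 region per class, 64x64, no noise: exact end-to-end recovery."""
    cfg = pt.PhantomConfig(image_size=(64, 64), noise_sigma=0.0, n_regions=1, seed=7)
    return pt.render_dataset(cfg)


@pytest.fixture(scope="session")
def default_dataset():
    """The default study conditions: 4+4 regions, 256x256, noisy."""
    return pt.render_dataset(pt.PhantomConfig(seed=1))


@pytest.fixture(scope="session")
def default_analyses(default_dataset):
    from polartissue.cli_io import analyze_dataset
    return analyze_dataset(default_dataset, pt.ideal_instrument())
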