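import numpy as np
import pytest

from spiderseg import phantom


@pytest.fixture(scope="session")
def small_spec():
    """A fast 64-px phantom spec used by most pipeline-level tests."""
    return phantom.PhantomSpec(image_size=64, n_normal=6, n_tumor=6, seed=11)


@pytest.fixture(scope="session")
def noise_free_spec():
    return phantom.PhantomSpec(image_size=96, n_normal=2, n_tumor=2,
                               noise_sd=0.0, seed=23)


@pytest.fixture(scope="session")
def tumor_sample(small_spec):
    return phantom.generate_phantom(small_spec, phantom.TUMOR)


@pytest.fixture(scope="session")
def normal_sample(small_spec):
    return phantom.generate_phantom(small_spec, phantom.NORMAL)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def cluster_data():
    """Two well-separated 2-D Gaussian clusters, 20 samples per class."""
    gen = np.random.default_rng(7)
    x0 = gen.normal([0.0, 0.0], 0.5, size=(20, 2))
    x1 = gen.normal([10.0, 10.0], 0.5, size=(20, 2))
    X = np.vstack([x0, x1])
    y = np.array([0] * 20 + [1] * 20)
    return X, y
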