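import numpy as np
import pytest

from neurocube.labels import default_atlas
from neurocube.phantom import PhantomSpec, generate_subject


@pytest.fixture(scope="session")
def scheme():
    return default_atlas()


@pytest.fixture(scope="session")
def small_phantom():
    """One jittered subject on a 32^3 grid (volume, score, family volumes)."""
    spec = PhantomSpec(grid_edge=32, seed=5)
    return generate_subject(spec, 0)


@pytest.fixture(scope="session")
def clean_phantom():
    """Zero-jitter, noise-free subject: exactly mirror-symmetric."""
    spec = PhantomSpec(grid_edge=32, scale_jitter=0.0, translate_jitter=0.0,
                       noise_sd=0.0, seed=5)
    return generate_subject(spec, 0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
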