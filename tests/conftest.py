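import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_phantom():
    """A small deterministic phantom pair shared across tests."""
    from plateseg.synthetic import PhantomConfig, generate_phantom

    return generate_phantom(PhantomConfig(shape=(16, 48, 48), n_cells=1, seed=3))


@pytest.fixture(scope="session")
def tiny_net():
    """A small deterministic 2-scale hybrid network."""
    from plateseg.model import tiny_model_config
    from plateseg.model_zoo import build_network

    return build_network(tiny_model_config(init_seed=0))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
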