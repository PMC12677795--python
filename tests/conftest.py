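import numpy as np
import pytest

from fuseg.synthetic import PhantomConfig, make_dataset


@pytest.fixture(scope="session")
def phantom_pairs():
    """Small deterministic phantom dataset shared across tests."""
    return make_dataset(PhantomConfig(size=64, seed=11), 8)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
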