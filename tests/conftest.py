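import numpy as np
import pytest

import presback as pb


@pytest.fixture(scope="session")
def cat():
    return pb.catalog()


@pytest.fixture(scope="session")
def small_linear_data(cat):
    """One modest presence-background draw from the linear logistic
    species, shared by read-only tests."""
    return pb.simulate_pb(cat.model("cat1_linear"), 1000, 10_000, seed=20240101)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
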