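import numpy as np
import pytest

from deprindex import SyntheticParams, generate_geography


@pytest.fixture(scope="session")
def small_geography():
    """A small but complete synthetic geography (2 states, 60 tracts)."""
    params = SyntheticParams(n_states=2, tracts_per_state=30, seed=11)
    return generate_geography(params)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
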