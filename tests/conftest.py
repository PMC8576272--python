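import numpy as np
import pytest

from ppisxgb import synthetic_data as sd


@pytest.fixture(scope="session")
def small_records():
    """Ten labelled synthetic proteins shared across read-only tests."""
    return sd.simulate_proteins(sd.SimConfig(n_proteins=10, length_min=20, length_max=60, seed=42))


@pytest.fixture(scope="session")
def medium_records():
    """Fifty labelled proteins at the generator's default conditions."""
    return sd.simulate_proteins(sd.SimConfig(n_proteins=50, seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
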