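import numpy as np
import pytest

from pulseseg.synthgen import NoiseParams, generate_record


@pytest.fixture(scope="session")
def noiseless_record():
    """One clean normal-type record with truth."""
    return generate_record("normal", noise=NoiseParams.none(), seed=1)


@pytest.fixture(scope="session")
def tiny_noiseless_dataset():
    """25 clean records over five morphologies: 20 train + 5 validation."""
    types = ["normal", "slippery", "string", "fine", "fine_string"]
    data = [
        generate_record(types[i % 5], noise=NoiseParams.none(), seed=i)
        for i in range(25)
    ]
    return data[:20], data[20:]


@pytest.fixture
def rng():
    return np.random.default_rng(0)
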