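import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests.oracles importable as `oracles`

from cidcharge import DEFAULT_CONSTANTS, SimParams, Tolerance, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def constants():
    return DEFAULT_CONSTANTS


@pytest.fixture(scope="session")
def tol_half():
    return Tolerance(0.5)


@pytest.fixture(scope="session")
def default_dataset():
    """A moderate generator-default dataset shared across tests (seed 0)."""
    params = SimParams(n_spectra=300, seed=0)
    collection, truths = generate_dataset(params)
    return params, collection, truths
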