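import warnings

import numpy as np
import pytest

import lba


@pytest.fixture(autouse=True)
def _quiet_near_constant():
    # scipy warns when bootstrap replicates or shrunken predictions are
    # nearly constant; those cases are part of what the tests probe.
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*nearly constant.*")
        yield


@pytest.fixture(scope="session")
def small_study():
    """A compact synthetic study shared by read-only tests."""
    return lba.generate_study(lba.SyntheticConfig(n_participants=120, seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
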