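import numpy as np
import pytest

from sacekit import synthetic as syn


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def als_sim():
    """One moderate synthetic cohort shared by read-only tests."""
    return syn.generate_cohort(syn.SyntheticTruth(), n=400, seed=11)


@pytest.fixture(scope="session")
def als_sim_mono():
    return syn.generate_cohort(
        syn.SyntheticTruth(), n=400, seed=13, monotonicity=True
    )
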