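import numpy as np
import pytest

from gmcausal.synth import build_default_model, simulate


@pytest.fixture(scope="session")
def default_model():
    return build_default_model()


@pytest.fixture(scope="session")
def default_cohort_20k(default_model):
    """One shared 20,000-subject draw from the ground-truth SCM."""
    return simulate(default_model, 20_000, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
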