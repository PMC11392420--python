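import numpy as np
import pytest

from proprio_disconnect import synthetic as syn
from proprio_disconnect.scoring import normative_fit


@pytest.fixture(scope="session")
def brain():
    """Default toy brain: 4 tract families (8 maps), 10 controls."""
    return syn.make_brain(1)


@pytest.fixture(scope="session")
def small_brain():
    return syn.make_brain(7, shape=(16, 20, 16), n_tracts=2, n_controls=4)


@pytest.fixture(scope="session")
def normative_model():
    """Normative model fitted on a modest control cohort (shared, read-only)."""
    cohort = syn.make_normative_cohort(11, n_controls=150, n_assessments=400)
    return normative_fit(list(cohort["session"]))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
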