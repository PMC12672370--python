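import numpy as np
import pytest

from cyclebrain.phantom import default_study_design


@pytest.fixture(scope="session")
def study():
    """One deterministic four-individual phantom study, shared across tests."""
    hormones, stacks, planted = default_study_design(seed=7)
    return {"hormones": hormones, "stacks": stacks, "planted": planted}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
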