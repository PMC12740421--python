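import numpy as np
import pytest

from mmdfnet.cohort import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """Reference cohort (358 cases / 200 controls) at a fixed seed."""
    return generate_cohort(CohortSpec(seed=1))


@pytest.fixture
def rng():
    return np.random.default_rng(0)
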