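import numpy as np
import pytest

import fuseroc as fr


@pytest.fixture(scope="session")
def default_cohort():
    """A full-size synthetic cohort under the default composition and model."""
    return fr.generate_cohort(fr.CohortConfig(seed=11))


@pytest.fixture()
def small_cohort():
    """A small mixed cohort for fast pipeline-level tests."""
    return fr.generate_cohort(fr.CohortConfig(12, 14, 30, seed=5))


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
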