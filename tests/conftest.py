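import numpy as np
import pytest

import hemipark as hp


@pytest.fixture(scope="session")
def atlas():
    return hp.generate_atlas()


@pytest.fixture(scope="session")
def brain_mask(atlas):
    return atlas.brain_mask()


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def default_cohort():
    spec = hp.CohortSpec(seed=7)
    return spec, hp.generate_cohort(spec)
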