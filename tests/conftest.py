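import numpy as np
import pytest

from mjdmri import spectroscopy as mrs
from mjdmri import synth

#: Single seed for every randomized check in the suite.
SEED = 12345


@pytest.fixture(scope="session")
def basis() -> mrs.BasisSet:
    return mrs.default_basis()


@pytest.fixture(scope="session")
def phantom_pair():
    """Default phantom with its ground-truth labels (shared, read-only)."""
    spec = synth.PhantomSpec(seed=SEED)
    image, labels = synth.make_phantom(spec)
    return spec, image, labels


@pytest.fixture(scope="session")
def mouse_cohort():
    return synth.make_cohort(synth.mouse_cohort_spec(seed=SEED))


@pytest.fixture(scope="session")
def human_cohort():
    return synth.make_cohort(synth.human_cohort_spec(seed=SEED))


@pytest.fixture()
def rng():
    return np.random.default_rng(SEED)
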