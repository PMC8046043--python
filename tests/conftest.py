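import numpy as np
import pytest

from dkipipe.acquisition import make_scheme
from dkipipe.cohort import default_cohort_spec, simulate_cohort
from dkipipe.dki_core import build_design


@pytest.fixture(scope="session")
def scheme():
    """The clinical two-shell protocol: 30 directions, b = 1000/2000, 5 b0."""
    return make_scheme(30, [1000, 2000], 5, seed=0)


@pytest.fixture(scope="session")
def design(scheme):
    return build_design(scheme)


@pytest.fixture(scope="session")
def cohort():
    """Default synthetic cohort at the study's group sizes (23/30/24)."""
    return simulate_cohort(default_cohort_spec(seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
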