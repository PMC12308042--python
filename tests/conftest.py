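import numpy as np
import pytest

from predsize.synthetic_cohort import make_cohort


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture(scope="session")
def minap_cohort_small():
    """A small ACS-like cohort for unit tests (not for calibration checks)."""
    return make_cohort("minap", n=4000, seed=101)


@pytest.fixture(scope="session")
def minap_cohort_20k():
    """Desk-scale ACS-like cohort shared by the simulation-level tests."""
    return make_cohort("minap", n=20_000, seed=11)


@pytest.fixture(scope="session")
def hf_cohort_20k():
    """Desk-scale heart-failure-like cohort."""
    return make_cohort("hf", n=20_000, seed=12)
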