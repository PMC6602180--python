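import numpy as np
import pytest

import cytara as ct
from cytara.predict import steady_state_params
from cytara.synth import DEFAULT_MEDIANS


@pytest.fixture(scope="session")
def pk():
    return ct.HIDAC_PK


@pytest.fixture(scope="session")
def consts(pk):
    return ct.ModelConstants.from_pk(pk)


@pytest.fixture(scope="session")
def median_params(consts):
    """Median cohort parameters with steady-state initial conditions."""
    return steady_state_params(ct.PDParameters(**DEFAULT_MEDIANS), consts)


@pytest.fixture(scope="session")
def d135(pk):
    return ct.build_schedule("D135")


@pytest.fixture(scope="session")
def dense_grid():
    return np.arange(0.0, 45.0001, 0.05)
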