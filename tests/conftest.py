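import numpy as np
import pytest

from agropast.config import ManagementPlan, ModelParameters
from agropast.rainfall import synthesize_historical


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)


@pytest.fixture(scope="session")
def historical():
    """A synthetic 60-year semi-arid annual rainfall record (fixed seed)."""
    return synthesize_historical(rng=np.random.default_rng(1))


@pytest.fixture
def small_params():
    """A 96-ha (20x20 patch) village: same dynamics, affordable runs.

    Household grain consumption scales with village area so the grain
    store behaves as it does at full size.
    """
    return ModelParameters(village_area=96.0,
                           household_consumption=60000.0 * 96 / 600)


@pytest.fixture
def default_plan():
    return ManagementPlan()
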