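import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")

from pocrm3d import (
    DesignParams,
    PartialOrderCRM,
    TrialData,
    build_default_grid,
    default_orderings,
    known_partial_order,
)


@pytest.fixture(scope="session")
def grid():
    return build_default_grid()


@pytest.fixture(scope="session")
def partial_order(grid):
    return known_partial_order(grid)


@pytest.fixture(scope="session")
def orderings(grid):
    return default_orderings(grid)


@pytest.fixture(scope="session")
def model(grid, orderings):
    """The calibrated trial design (shared; fits are cheap, setup is not)."""
    return PartialOrderCRM(grid=grid, orderings=orderings, design=DesignParams())


@pytest.fixture()
def rng():
    return np.random.default_rng(20240101)
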