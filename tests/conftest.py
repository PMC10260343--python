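import numpy as np
import pytest

from shiftcrm import (
    Combination,
    ShiftCrmConfig,
    ShiftCrmDesign,
    TrialState,
    illustration_scenario,
)


def make_state(records, config=None):
    """TrialState from a list of (row, level, dlt) triples."""
    config = config or ShiftCrmConfig()
    state = TrialState(grid=config.grid())
    for row, level, dlt in records:
        state.add(Combination(row, level), dlt)
    return state


@pytest.fixture(scope="session")
def config():
    return ShiftCrmConfig()


@pytest.fixture(scope="session")
def design():
    return ShiftCrmDesign()


@pytest.fixture(scope="session")
def models(design):
    return design.models


@pytest.fixture(scope="session")
def illustration():
    return illustration_scenario()


@pytest.fixture()
def interim_state(config):
    """The worked example's first five patients: four clean escalations along
    row 1 and the first DLT at row-1 level 5."""
    return make_state(
        [(1, 1, 0), (1, 2, 0), (1, 3, 0), (1, 4, 0), (1, 5, 1)], config
    )
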