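import numpy as np
import pytest

from anfga.fuzzy_preference import (
    IssueDomain,
    PreferenceProfile,
    TrapezoidMembership,
)
from anfga.ga_opponent_model import GAParams
from anfga.scenarios_harness import Scenario, table2_fixture


@pytest.fixture
def table2():
    return table2_fixture()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def unit_domain():
    return IssueDomain("x", 0.0, 1.0, 0.1)


@pytest.fixture
def small_scenario():
    """Two issues on [0, 1] with an 11-point grid each (121 offers total)."""
    domains = (
        IssueDomain("u", 0.0, 1.0, 0.1),
        IssueDomain("v", 0.0, 1.0, 0.1),
    )
    pa = PreferenceProfile(
        [0.5, 0.5],
        [
            TrapezoidMembership(0.0, 0.2, 0.4, 0.8),
            TrapezoidMembership(0.1, 0.3, 0.5, 0.9),
        ],
    )
    da = PreferenceProfile(
        [0.4, 0.6],
        [
            TrapezoidMembership(0.2, 0.5, 0.7, 1.0),
            TrapezoidMembership(0.3, 0.6, 0.8, 1.0),
        ],
    )
    return Scenario(domains=domains, pa=pa, da=da, label="small")


@pytest.fixture
def fast_ga():
    """Cheap GA settings for unit tests."""
    return GAParams(population_size=20, max_iteration=5)
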