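import numpy as np
import pytest

from lanelab import (
    CorridorGeometry,
    SimulationConfig,
    run_simulation,
)

RING = CorridorGeometry(2.0, 4.5)

# a huge annulus whose walls sit far beyond the anticipation horizon:
# free-flow behaviour is effectively straight-line walking
OPEN_FIELD = CorridorGeometry(1.0, 1000.0)


@pytest.fixture(scope="session")
def runs_n60():
    """Ten seeded 60 s bidirectional runs at N = 60, sigma = 0.16."""
    return [run_simulation(SimulationConfig(n=60, sigma=0.16, duration=60.0, seed=s))
            for s in range(1, 11)]


@pytest.fixture(scope="session")
def runs_n30():
    """Ten seeded 60 s bidirectional runs at N = 30, sigma = 0.16."""
    return [run_simulation(SimulationConfig(n=30, sigma=0.16, duration=60.0, seed=s))
            for s in range(1, 11)]


@pytest.fixture(scope="session")
def short_run_n20():
    """One quick 20 s run for smoke-level checks."""
    return run_simulation(SimulationConfig(n=20, sigma=0.16, duration=20.0, seed=7))


def assert_partition(partition, ids):
    """Every id exactly once across disjoint clusters."""
    seen = [x for part in partition for x in part]
    assert sorted(seen) == sorted(ids)
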