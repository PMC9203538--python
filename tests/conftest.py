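import numpy as np
import pytest

from synaptoquant import simulate


@pytest.fixture(scope="session")
def mesf_levels():
    return [0.0, 1e3, 1e4, 1e5, 1e6]


@pytest.fixture(scope="session")
def mesf_ladder(mesf_levels):
    return simulate.simulate_mesf_ladder(mesf_levels, n_events=5000, cv=0.3, seed=11)


@pytest.fixture(scope="session")
def small_design():
    """Reduced co-culture design for fast unit tests."""
    return simulate.SimulationDesign(
        doses=[0.0, 62.5, 250.0, 1000.0],
        n_events_per_population=2000,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_coculture(small_design):
    return simulate.simulate_coculture(small_design)


@pytest.fixture(scope="session")
def dose_ladder():
    return np.array([0.0] + [1000.0 / 2 ** k for k in reversed(range(8))])
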