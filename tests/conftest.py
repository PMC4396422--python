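import time

import pytest

from crossfba import (
    ScreenConfig,
    SimulationConfig,
    make_environment,
    make_toy_pair,
    run_screen,
    simulate_community,
)
from crossfba.synthetic_models import ToyParams


@pytest.fixture(scope="session")
def toy_params():
    return ToyParams()


@pytest.fixture(scope="session")
def toy_pair():
    """The (E-like, S-like) fixture models with default parameters."""
    return make_toy_pair()


@pytest.fixture(scope="session")
def toy_e(toy_pair):
    return toy_pair[0]


@pytest.fixture(scope="session")
def toy_s(toy_pair):
    return toy_pair[1]


@pytest.fixture(scope="session")
def study_sim():
    """The study's simulation conditions: 10 h horizon, dt 0.1 h, Km 10 uM,
    Vmax 10 mmol/gDW/h, death rate 0.01/h."""
    return SimulationConfig()


@pytest.fixture(scope="session")
def coop_traj(toy_pair, study_sim):
    return simulate_community(list(toy_pair), make_environment("cooperation"), study_sim)


@pytest.fixture(scope="session")
def comp_traj(toy_pair, study_sim):
    return simulate_community(list(toy_pair), make_environment("competition"), study_sim)


@pytest.fixture(scope="session")
def toy_screen(toy_pair):
    """Full toy knockout screen under both pair conditions (plus monoculture
    essentiality calls), with the wall time it took."""
    config = ScreenConfig()
    t0 = time.perf_counter()
    result = run_screen(toy_pair[0], toy_pair[1], config)
    elapsed = time.perf_counter() - t0
    return result, config, elapsed
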