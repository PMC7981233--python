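import numpy as np
import pytest
from shapely.geometry import LineString, box

from anole_spatgen.io import HabitatMap
from anole_spatgen.simulate import SimConfig, simulate_population


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture(scope="session")
def square_park():
    """Hand-built 100x100 park with four small bushes on known walls."""
    bushes = {
        1: box(10.0, 0.0, 16.0, 2.0),  # south wall
        2: box(60.0, 0.0, 66.0, 2.0),  # south wall, 50 m from bush 1
        3: box(98.0, 40.0, 100.0, 46.0),  # east wall
        4: box(30.0, 98.0, 36.0, 100.0),  # north wall
    }
    fence = LineString([(0, 0), (100, 0), (100, 100), (0, 100), (0, 0)])
    return HabitatMap(bushes, fence)


@pytest.fixture(scope="session")
def sim_small():
    """A compact but fully featured simulated park shared across tests."""
    cfg = SimConfig(seed=42, founder_n=40, n_cohorts=6, capture_prob=0.8,
                    recruits_per_female=2.0)
    return simulate_population(cfg)


@pytest.fixture(scope="session")
def sim_full_capture():
    """Perfect detection and forced male dispersal: every lizard sampled."""
    cfg = SimConfig(seed=7, founder_n=40, n_cohorts=6, capture_prob=1.0,
                    recruits_per_female=2.0)
    return simulate_population(cfg)
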