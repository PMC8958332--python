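import numpy as np
import pytest

from pcunits.graphs import demo_unit
from pcunits.synthetic import SimulationConfig, generate_dag_population, simulate_unit_timeseries


@pytest.fixture
def demo():
    """Two-peak, three-splice unit (a1->s1, a2->s2, a2->s3, all s->p)."""
    return demo_unit()


@pytest.fixture
def rng():
    return np.random.default_rng(20240517)


@pytest.fixture(scope="session")
def small_population():
    """A small synthetic population with its simulated series (seeded)."""
    cfg = SimulationConfig(n_units=8, seed=11)
    truth = generate_dag_population(cfg)
    series = simulate_unit_timeseries(truth, cfg)
    return cfg, truth, series
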