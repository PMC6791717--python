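import numpy as np
import pytest

import labelchase as lc


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture
def noise_free_config():
    """Agent-mode config with every noise source switched off."""
    return lc.SimConfig(n_cells=1000, seed=7).noise_free()


@pytest.fixture
def homogeneous():
    """Single subpopulation dividing at the schedule's base rate."""
    return (lc.SubpopulationSpec(fraction=1.0, rate_multiplier=1.0),)


def constant_schedule(p: float, horizon: float = 10_000.0) -> "lc.RateSchedule":
    return lc.RateSchedule(breakpoints=(0.0, horizon), rates=(p,))


@pytest.fixture
def default_flow_sample():
    """A measured flow sample from the default day-0 population."""
    config = lc.SimConfig(n_cells=4000, seed=11)
    rng = np.random.default_rng(11)
    pop = lc.build_population(config, rng=rng)
    return lc.measure_flow(pop, config, rng)
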