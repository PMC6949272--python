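import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "repro",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("repro")

from beecast import synthetic, timeseries
from beecast.rnn import TrainingConfig


@pytest.fixture(scope="session")
def sim_config():
    """A 10-day simulated campaign with the default study conditions."""
    return synthetic.SimulationConfig(n_days=10, seed=11)


@pytest.fixture(scope="session")
def simulated(sim_config):
    weather = synthetic.simulate_weather(sim_config)
    events, truth = synthetic.simulate_events(sim_config, weather)
    return weather, events, truth


@pytest.fixture(scope="session")
def panel(sim_config, simulated):
    weather, events, _ = simulated
    activity = timeseries.compute_activity_level(
        events, sim_config.n_bees, weather.index
    )
    return timeseries.build_panel(activity, weather)


@pytest.fixture
def fast_training():
    """Short training budget for structural tests (not accuracy checks)."""
    return TrainingConfig(epochs=15)
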