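import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from metkit.synthetic import (  # noqa: E402
    ChannelModel,
    FluidJetModel,
    MovieSpec,
    StackSpec,
    TraceProtocol,
    simulate_bundle_movie,
    simulate_met_traces,
)


@pytest.fixture(scope="session")
def default_jet():
    return FluidJetModel()


@pytest.fixture(scope="session")
def noise_free_met_sim(default_jet):
    """Noise-free trace set over the full voltage series (shared: slow)."""
    channel = ChannelModel(noise_sd=0.0)
    protocol = TraceProtocol()
    return simulate_met_traces(channel, default_jet, protocol, seed=0)


@pytest.fixture(scope="session")
def noise_free_movie(default_jet):
    """Noise-free 900-frame movie with a 0.3 nN step (shared: slow)."""
    spec = MovieSpec(photon_scale=np.inf)
    return simulate_bundle_movie(spec, default_jet, [(0.3, 60.0, 90.0)], seed=0)


@pytest.fixture(scope="session")
def default_stack_spec():
    return StackSpec()
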