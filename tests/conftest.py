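import numpy as np
import pytest
from hypothesis import settings

import nearsource as ns

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_cfg():
    return ns.ScenarioConfig(seed=11)


@pytest.fixture(scope="session")
def default_route(default_cfg):
    return ns.make_route(default_cfg)


@pytest.fixture(scope="session")
def small_cfg():
    """Tiny route (one 400 m polyline east of a small yard) for fast
    aggregated-table draws."""
    return ns.ScenarioConfig(
        seed=7,
        yard_size_m=(100.0, 400.0),
        route_offsets_m=(60.0,),
        segment_length_m=50.0,
    )


@pytest.fixture(scope="session")
def quiet_session():
    """A noiseless, plume-free 2 h session whose concentration is exactly
    background * exp(beta0)."""
    cfg = ns.ScenarioConfig(
        seed=3,
        true_beta=(0.0, 0.0, 0.0, 0.0, 0.0),
        plume_rate_per_h=0.0,
        noise_sdlog=0.0,
        sample_interval_s=2.0,
    )
    route = ns.make_route(cfg)
    wind = ns.simulate_wind(cfg, 12)
    session, truth = ns.simulate_session(cfg, route, wind, duration_h=2.0)
    return session, truth
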