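import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def quiet_run():
    """One deterministic quiescent 48-h simulation shared across tests."""
    from rnaero.synthetic_room import RoomConfig, simulate_room

    cfg = RoomConfig(baseline_total_gsd=1.0, seed=11)
    return cfg, simulate_room(cfg, duration_h=48.0, dt_s=60.0)
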