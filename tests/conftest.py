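import pytest
from hypothesis import HealthCheck, settings

from reporterscore import SimConfig, simulate_replica

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def replica():
    """Fixed-seed replica dataset: (ko_stats, pathway sets, truth table)."""
    return simulate_replica(SimConfig(seed=1))
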