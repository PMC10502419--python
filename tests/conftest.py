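import pytest
from hypothesis import HealthCheck, settings

import retinasim as rs

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def rf63() -> rs.RFMap:
    """Balanced 3x3 receptive-field map on the canonical 63x63 array."""
    return rs.build_rfmap(63, 63, 3, 3, donor_fraction=0.25)


@pytest.fixture(scope="session")
def scene_cache():
    """Memoized canonical scenarios (scene generation is deterministic)."""
    cache = {}

    def get(name: str, seed: int = 1):
        key = (name, seed)
        if key not in cache:
            cache[key] = rs.scenario(name, seed=seed)
        return cache[key]

    return get
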