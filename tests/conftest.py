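import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_grid():
    from topolink.topology import ThresholdGrid

    return ThresholdGrid.default(50)


@pytest.fixture(scope="session")
def coarse_grid():
    """8 evenly spaced thresholds, enough to exercise snapping."""
    from topolink.topology import ThresholdGrid

    return ThresholdGrid(np.linspace(0.0, 255.0, 8))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
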