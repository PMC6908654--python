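import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_geometry():
    """10x10 toy scan for hand-checkable coordinate arithmetic."""
    from ccvoids import ScanGeometry

    return ScanGeometry(field_of_view_mm=12.0, pixels_per_side=10)


@pytest.fixture
def full_geometry():
    """The study geometry: 12 mm over 500 px (24-um pitch)."""
    from ccvoids import ScanGeometry

    return ScanGeometry()
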