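from datetime import datetime, timezone

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from vegnet import Scan

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20120801)


def make_scan(ranges, *, instrument_id="VN5", truncated=False, timestamp=None, zenith=57.5):
    """Build a scan from a plain list of ranges (0.0 = gap)."""
    ranges = np.asarray(ranges, dtype=float)
    n = ranges.size
    az = np.round(np.arange(n) * (360.0 / n), 1) % 360.0
    return Scan(
        instrument_id=instrument_id,
        timestamp=timestamp or datetime(2013, 3, 1, 22, 0, tzinfo=timezone.utc),
        zenith_deg=zenith,
        azimuth_deg=az,
        range_m=ranges,
        truncated=truncated,
    )


@pytest.fixture
def scan_factory():
    return make_scan
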