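import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from groupalign import Peak, PeakList


@pytest.fixture
def small_run() -> PeakList:
    """Three peaks, two coeluting — the hand-traced greedy-grouping case."""
    return PeakList(
        "r1",
        [
            Peak("p1", 100.0, 10.0, 100.0),
            Peak("p2", 101.0, 10.5, 50.0),
            Peak("p3", 102.0, 20.0, 80.0),
        ],
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20230917)
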