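import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pentascore.config import RunConfig
from pentascore.synthgen import DrawingSpec, generate_trace

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def cfg() -> RunConfig:
    return RunConfig()


@pytest.fixture(scope="session")
def perfect_drawing(cfg):
    """A flawless interlocking-pentagon trace with its ground truth."""
    return generate_trace(DrawingSpec(seed=11), cfg)


def make_trace(e, x=None, y=None, dt=0.02):
    """Small hand-built trace with the given event sequence."""
    from pentascore.sensor_io import SensorTrace

    e = np.asarray(e, dtype=int)
    n = len(e)
    if x is None:
        x = np.linspace(10, 10 + n - 1, n)
    if y is None:
        y = np.full(n, 20.0)
    return SensorTrace(np.arange(n) * dt, np.asarray(x, float), np.asarray(y, float), e)
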