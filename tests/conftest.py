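import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from meioquant import EllipseParams

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def canonical_ellipse() -> EllipseParams:
    """The initialization ellipse: full axes 65 x 35 nm at the origin."""
    return EllipseParams(0.0, 0.0, 65.0, 35.0, 0.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
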