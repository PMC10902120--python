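import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from desst2.signal_models import AcquisitionParams


@pytest.fixture
def acq() -> AcquisitionParams:
    """Default acquisition: TR 20 ms, TE 5 ms, flip 20 deg."""
    return AcquisitionParams()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260930)
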