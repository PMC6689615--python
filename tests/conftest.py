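import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def warm_kernel():
    """Trigger the one-off jit compilation before timing-sensitive tests."""
    from homeoca import Params, run_session

    run_session(Params(r=0.0, d=0.5, a=0.0), 4, 2, seed=0)
    return True


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)
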