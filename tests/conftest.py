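import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def montage8():
    from phasetopo import standard_montage

    return standard_montage("10-10-8ch")


@pytest.fixture(scope="session")
def montage19():
    from phasetopo import standard_montage

    return standard_montage("10-20-19ch")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
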