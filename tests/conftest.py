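import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "package",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("package")


@pytest.fixture(scope="session")
def default_cfg():
    from chromostat.config import default_config

    return default_config()


@pytest.fixture(scope="session")
def default_plant(default_cfg):
    return default_cfg.build_plant()


@pytest.fixture(scope="session")
def gdh_plant(default_cfg):
    return default_cfg.build_plant(with_gdh=True)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
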