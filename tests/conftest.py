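import pytest
from hypothesis import HealthCheck, settings

from srmtdm.assay import build_cetuximab_assay
from srmtdm.simulate import SimConfig

settings.register_profile(
    "srmtdm",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("srmtdm")


@pytest.fixture(scope="session")
def assay():
    return build_cetuximab_assay()


@pytest.fixture()
def noise_free_config():
    return SimConfig(seed=0, noise_cv=0.0, rt_jitter_sd=0.0)
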