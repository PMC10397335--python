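import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pivbench import RenderParams, VicsekParams

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def default_params() -> VicsekParams:
    """The study conditions: L=5 (615 px), N=300, v0=0.03, r=0.5."""
    return VicsekParams()


@pytest.fixture
def small_params() -> VicsekParams:
    """A 246-px box with 40 agents: same densities, desk-scale cost."""
    return VicsekParams(L=2.0, N=40)


@pytest.fixture
def small_render(small_params) -> RenderParams:
    return RenderParams(gamma_img=small_params.gamma_img)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
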