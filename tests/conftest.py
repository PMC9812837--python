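import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

#: the study-like survey design: six margin observations at each of five
#: survey years, breakpoint 2006, post-break slope 5.48 km/yr, SD 17.6 km
DESIGN_YEARS = np.array([1985.0, 2003.0, 2013.0, 2019.0, 2021.0])
PSI_TRUE = 2006.0
SLOPE_TRUE = 5.48
SIGMA_TRUE = 17.6
BETA0_TRUE = 162.5


@pytest.fixture(scope="session")
def margin_x():
    return np.repeat(DESIGN_YEARS, 6)


@pytest.fixture(scope="session")
def margin_mean(margin_x):
    return BETA0_TRUE + SLOPE_TRUE * np.maximum(margin_x - PSI_TRUE, 0.0)


def margin_draw(margin_x, margin_mean, seed):
    rng = np.random.default_rng(seed)
    return margin_mean + SIGMA_TRUE * rng.standard_normal(len(margin_x))


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)
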