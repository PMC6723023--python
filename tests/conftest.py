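import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pulpcolor.synthetic import SyntheticSpec, generate_fruit_dataset

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


#: published blackberry anthocyanin calibration, used as ground truth in
#: parameter-recovery simulations throughout the suite
BLACKBERRY_TAC_COEFFS = (1644.47, -13.53, -12.56, 18.42)
BLACKBERRY_COLOR_MEANS = (10.68, 13.80, 4.95)
BLACKBERRY_COLOR_SDS = (2.23, 3.90, 1.70)


def blackberry_spec(**overrides) -> SyntheticSpec:
    defaults = dict(
        fruit_label="Blackberry",
        analyte="TAC",
        true_coefficients=BLACKBERRY_TAC_COEFFS,
        color_means=BLACKBERRY_COLOR_MEANS,
        color_sds=BLACKBERRY_COLOR_SDS,
        noise_sd=50.0,
        seed=1,
    )
    defaults.update(overrides)
    return SyntheticSpec(**defaults)


@pytest.fixture
def noisy_dataset():
    """45-row blackberry-like dataset with Gaussian content noise."""
    return generate_fruit_dataset(blackberry_spec())


@pytest.fixture
def noiseless_dataset():
    return generate_fruit_dataset(blackberry_spec(noise_sd=0.0))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
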