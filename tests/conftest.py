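import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from tactile_filehne.observer import ObserverParams, calibrate_prior_variance

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

#: Prior variance that places the proprioceptive-only probit slope at 0.02
#: for a likelihood variance of 34 mm^2/s^2.
CALIBRATED_PRIOR = calibrate_prior_variance(0.02, 34.0)


@pytest.fixture(scope="session")
def calibrated_params() -> ObserverParams:
    """Observer with the calibrated prior and the reference variances."""
    return ObserverParams.single_prior(CALIBRATED_PRIOR, 34.0, 11.0, v_pursuit=10.8)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20150928 % 2**31)
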