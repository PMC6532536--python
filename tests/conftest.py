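import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import kneefit as kf

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_cfg():
    """Standard surrogate conditions at reduced trial count (fast unit runs)."""
    return kf.standard_surrogate_config(n_trials=30, seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_cfg):
    return kf.simulate_dataset(small_cfg)


@pytest.fixture(scope="session")
def small_curve(small_dataset):
    return kf.reduce_to_curve(small_dataset)


@pytest.fixture(scope="session")
def hs_cfg():
    """Hard-sigmoid-template surrogate at reduced trial count."""
    return kf.hard_sigmoid_surrogate_config(n_trials=30, seed=17)


@pytest.fixture(scope="session")
def hs_dataset(hs_cfg):
    return kf.simulate_dataset(hs_cfg)


@pytest.fixture
def noise_free_curve():
    """Exact composed-logistic curve points with a known sigma (no sampling)."""
    params = kf.LogisticParams(a=10.0, b=60.0, c=11.89)
    noise = kf.NoiseModel(kf.QUADRATURE, 2.8284)
    x = np.linspace(-30.0, 130.0, 22)
    return kf.LevelResponseCurve(x, kf.composed_model(x, params, noise), noise)
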