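import numpy as np
import pytest

from wbec.containers import MOUModel
from wbec.model import model_covariances
from wbec.synthetic import random_stable_model


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def uncoupled_model():
    """3-region MOU with zero coupling: covariances known in closed form."""
    return MOUModel(
        ec=np.zeros((3, 3)),
        sigma=np.array([1.0, 2.0, 0.5]),
        tau_seconds=1.5,
    )


@pytest.fixture
def small_true_model():
    """A random stable 10-region model with its analytic covariances."""
    model = random_stable_model(10, density=0.3, tau_seconds=2.0, seed=11)
    cov = model_covariances(model, lag_trs=1, tr_seconds=2.0)
    return model, cov
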