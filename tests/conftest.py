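import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", deadline=None, derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")

from slsim.classifier import ModelSpec, TrainConfig
from slsim.synth import CLASSES, generate_cohort


@pytest.fixture(scope="session")
def model_spec():
    return ModelSpec()


@pytest.fixture(scope="session")
def small_cohort():
    """60 images, 10 per class — the smallest fixture worth training on."""
    return generate_cohort({c: 10 for c in CLASSES}, cohort="train", seed=11)


@pytest.fixture(scope="session")
def train_config():
    return TrainConfig(seed=3)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
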