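import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from marrowmeter.cli import make_training_set, make_validation_slides
from marrowmeter.model import ModelConfig, build_model, train_on_arrays

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.function_scoped_fixture],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def training_set():
    """200 synthetic 64-px tiles spanning the cellularity range."""
    return make_training_set(200, 64, seed=1)


@pytest.fixture(scope="session")
def validation_slides():
    """20 synthetic 256-px slides, mask-derived truths spanning 10-95%."""
    return make_validation_slides(20, 256, seed=1)


@pytest.fixture(scope="session")
def trained(training_set):
    """Default-conditions model: 10 epochs, no augmentation; with history."""
    images, labels = training_set
    model = build_model(ModelConfig(input_size=64, epochs=10, seed=1))
    model, history = train_on_arrays(
        model, images[20:], labels[20:], images[:20], labels[:20]
    )
    return model, history


@pytest.fixture(scope="session")
def trained_model(trained):
    return trained[0]


@pytest.fixture(scope="session")
def robust_model(training_set):
    """Model trained with mild scanner-style jitter for rescan robustness."""
    images, labels = training_set
    model = build_model(
        ModelConfig(
            input_size=64,
            epochs=15,
            color_jitter=10.0,
            gain_jitter=0.04,
            blur_jitter=1.0,
            seed=1,
        )
    )
    model, _ = train_on_arrays(model, images[20:], labels[20:], images[:20], labels[:20])
    return model


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
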