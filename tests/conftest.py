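import numpy as np
import pytest
from hypothesis import settings

from wheelbouts import synthetic
from wheelbouts.evaluate import train_reference_model

settings.register_profile("deterministic", derandomize=True, max_examples=50)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def reference_model():
    """The study-protocol classifier: trained on one simulated holder-phone
    trial, early-stopped on a second trial's validation split (seed 1)."""
    return train_reference_model(seed=1)


@pytest.fixture(scope="session")
def series1_run():
    """One series1-style recording + truth from the training device."""
    return synthetic.generate_recording(
        synthetic.preset_scenario("series1"), synthetic.device_catalog()[0], seed=123
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
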