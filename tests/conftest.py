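import numpy as np
import pytest

from mtsimg import MTSDataset, MTSInstance, SynthConfig, generate_synthetic


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture(scope="session")
def small_dataset():
    """20 instances, 2 channels, strongly separable; shared across tests."""
    return generate_synthetic(
        SynthConfig(n_instances=20, m=2, length_range=(40, 60), seed=11)
    )


@pytest.fixture
def tiny_instance():
    chans = np.array([[0.0, 1.0, 2.0, 3.0], [3.0, 2.0, 1.0, 0.0]])
    return MTSInstance("tiny", chans, 0)
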