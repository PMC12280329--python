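import numpy as np
import pytest

from cystovit import EncoderConfig, ImageModel, PhantomConfig, generate_exams


@pytest.fixture(scope="session")
def tiny_model() -> ImageModel:
    """Untrained tiny encoder shared by structural tests."""
    return ImageModel(EncoderConfig.tiny(), seed=0)


@pytest.fixture(scope="session")
def small_exams():
    """A handful of deterministic phantom exams."""
    return generate_exams(PhantomConfig(n_patients=6, seed=123))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(99)
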