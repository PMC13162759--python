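import numpy as np
import pytest

from narousal import generate_latent_arousal
from narousal.montage import standard_montage
from narousal.synthetic import generate_luminance


@pytest.fixture(scope="session")
def latent():
    return generate_latent_arousal(600, seed=11)


@pytest.fixture(scope="session")
def luminance():
    return generate_luminance(600, seed=12)


@pytest.fixture(scope="session")
def montage32():
    return standard_montage()


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
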