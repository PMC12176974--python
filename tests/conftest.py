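import numpy as np
import pytest

from affinerf import StimulusSpec, make_stimulus


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def noise_image_128():
    return make_stimulus(
        StimulusSpec("band_limited_noise", size=128, cutoff=8.0, seed=1)
    )


@pytest.fixture(scope="session")
def noise_image_96():
    return make_stimulus(
        StimulusSpec("band_limited_noise", size=96, cutoff=8.0, seed=3)
    )
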