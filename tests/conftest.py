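import numpy as np
import pytest

from cfasim import PopulationModel, compute_moments, generate_sample


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def clean_fit_moments(rng):
    """Well-behaved seeded sample: strong loadings, moderate size."""
    model = PopulationModel.equal_loading(0.4, 6)
    return compute_moments(generate_sample(model, 500, rng))
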