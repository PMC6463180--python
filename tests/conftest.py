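import numpy as np
import pytest

from neoref import (chb_reference_model, generate_grid, hct_reference_model)


@pytest.fixture
def chb_model():
    return chb_reference_model()


@pytest.fixture
def hct_model():
    return hct_reference_model()


@pytest.fixture(params=["chb", "hct"])
def any_model(request, chb_model, hct_model):
    return chb_model if request.param == "chb" else hct_model


@pytest.fixture
def chb_grid(chb_model):
    """Noise-free 77-point default-layout grid from the cHb preset."""
    return generate_grid(chb_model)


@pytest.fixture
def full_grid_points():
    """Integer GA 22..42 crossed with PNA 0..28 (609 points)."""
    return np.arange(22.0, 43.0), np.arange(0.0, 29.0)
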