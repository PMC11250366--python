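import numpy as np
import pytest

from mfias.optics import OpticalConfig


@pytest.fixture(scope="session")
def cfg():
    """Reference detection path: NA 0.3, 0.5 um emission, 2 um pixels."""
    return OpticalConfig(numerical_aperture=0.3, wavelength_um=0.5, pixel_size_sample_um=2.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
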