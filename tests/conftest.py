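import numpy as np
import pytest

from rwpsf import OpticalSetup, SamplingGrid

CIRCULAR = (1 / np.sqrt(2), 1j / np.sqrt(2))


@pytest.fixture
def high_na_setup():
    """Oil-immersion high-NA preset (NA 1.3, ni 1.5, 632 nm)."""
    return OpticalSetup(
        na=1.3, wavelength=632.0, n_sample=1.5, n_immersion=1.5, polarisation=CIRCULAR
    )


@pytest.fixture
def low_na_setup():
    """Air low-NA preset (NA 0.5, n 1.0, 632 nm)."""
    return OpticalSetup(na=0.5, wavelength=632.0, polarisation=CIRCULAR)


@pytest.fixture
def small_grid():
    """Coarse sampling for fast unit tests."""
    return SamplingGrid(pupil_size=65, out_size=31, pixel_size=50.0)
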