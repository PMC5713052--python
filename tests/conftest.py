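import numpy as np
import pytest

from corneahsi import SpectrumModel


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_model():
    """16-band spectral model for fast scene generation."""
    return SpectrumModel(wavelengths=np.linspace(400.0, 1000.0, 16))


@pytest.fixture
def noise_free_model():
    return SpectrumModel(wavelengths=np.linspace(400.0, 1000.0, 16), noise_sd=0.0)
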