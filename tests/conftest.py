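import pytest

from spectrait.bands import BandGrid, default_grid
from spectrait.preprocess import SpectrumSet, trim_and_normalize
from spectrait.simulate import SpectralModelParams, simulate_spectrum_set


@pytest.fixture(scope="session")
def grid256() -> BandGrid:
    return default_grid()


@pytest.fixture(scope="session")
def small_set() -> SpectrumSet:
    """64 synthetic measured spectra at the default study conditions."""
    sset, _ = simulate_spectrum_set(64, seed=1)
    return sset


@pytest.fixture(scope="session")
def norm_set(small_set) -> SpectrumSet:
    """The 64-sample set trimmed to 247 bands and min-max normalized."""
    return trim_and_normalize(small_set)


@pytest.fixture(scope="session")
def noiseless_params() -> SpectralModelParams:
    return SpectralModelParams(noise_sd=0.0, variety_sd=0.0)
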