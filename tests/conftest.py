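import numpy as np
import pytest

from nirstew.spectra_io import SpectraSet


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_spectra(values, wavelengths=None, band="NIR", ids=None):
    """Small SpectraSet builder for unit tests."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if wavelengths is None:
        wavelengths = np.arange(values.shape[1], dtype=float)
    if ids is None:
        ids = [f"s{i}" for i in range(values.shape[0])]
    return SpectraSet(np.asarray(wavelengths, float), values, band, ids)
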