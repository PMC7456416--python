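import numpy as np
import pytest

import cdvalid as cv


@pytest.fixture(scope="session")
def basis():
    """Seeded three-class fixture basis with canonical far-UV band shapes."""
    return cv.make_fixture_basis(seed=1)


@pytest.fixture(scope="session")
def correct_spectrum(basis):
    """The correct CD signal: 30/40/30 helix/strand/other on the basis."""
    return cv.make_correct_spectrum(basis)


@pytest.fixture(scope="session")
def contamination(correct_spectrum):
    return cv.make_contamination(correct_spectrum, seed=1)


@pytest.fixture(scope="session")
def benchmark():
    """(models, spectra, basis, contamination, correct) at seed 1."""
    return cv.build_benchmark(seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_spectrum(rng, n=40, lo=180.0, label="rnd"):
    wl = lo + np.arange(n, dtype=float)
    return cv.CDSpectrum(wl, rng.normal(0.0, 5.0, size=n), label)
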