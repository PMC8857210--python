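import numpy as np
import pytest

from mospade.optics import HermiteGaussianBasis, PSFModel


@pytest.fixture(scope="session")
def psf1():
    return PSFModel(1, 1.0)


@pytest.fixture(scope="session")
def basis40(psf1):
    return HermiteGaussianBasis(psf1.sigma, 40, 1)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260928)
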