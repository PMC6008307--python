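import numpy as np
import pytest

from phaseloc.optics import OpticsConfig, PupilModel


@pytest.fixture(scope="session")
def optics64() -> OpticsConfig:
    return OpticsConfig(fft_size=64)


@pytest.fixture(scope="session")
def optics32() -> OpticsConfig:
    return OpticsConfig(fft_size=32)


@pytest.fixture(scope="session")
def flat_pupil(optics64) -> PupilModel:
    """Unaberrated, unblurred pupil on the default 64-pixel grid."""
    return PupilModel(optics=optics64, coeffs=np.zeros(12), blur_sigma=0.0)


@pytest.fixture(scope="session")
def astig_pupil(optics64) -> PupilModel:
    """Astigmatic pupil (c5 = 1 rad), the simplest engineered PSF."""
    coeffs = np.zeros(12)
    coeffs[5 - 4] = 1.0
    return PupilModel(optics=optics64, coeffs=coeffs, blur_sigma=0.7)


@pytest.fixture(scope="session")
def saddle_pupil(optics64) -> PupilModel:
    """Saddle-point-like pupil (spherical c11 = 2 rad) for a ~4 um range."""
    coeffs = np.zeros(12)
    coeffs[11 - 4] = 2.0
    return PupilModel(optics=optics64, coeffs=coeffs, blur_sigma=0.7)


@pytest.fixture(scope="session")
def saddle_templates(saddle_pupil):
    from phaseloc.detect import build_templates
    return build_templates(saddle_pupil, -2200.0, 2200.0, window=25)
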