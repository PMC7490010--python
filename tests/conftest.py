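import numpy as np
import pytest

from punckit import (
    AcquisitionParams,
    DetectionParams,
    KineticsParams,
    ReleaseKineticsParams,
)


@pytest.fixture
def small_acq() -> AcquisitionParams:
    """A small, fast field: 96x96 px, 3 cells x 8 puncta, 2 min trial."""
    return AcquisitionParams(
        trial_duration=120.0,
        image_shape=(96, 96),
        cells_per_field=3,
        puncta_per_cell=8,
    )


@pytest.fixture
def noise_free_acq() -> AcquisitionParams:
    """Full-size field with noise and bleaching disabled (detector oracle)."""
    return AcquisitionParams(poisson_gain=None, read_noise_sd=0.0, bleach_rate=0.0)


@pytest.fixture
def default_det() -> DetectionParams:
    return DetectionParams()


@pytest.fixture
def default_kinp() -> KineticsParams:
    return KineticsParams()


@pytest.fixture
def vehicle_kin() -> ReleaseKineticsParams:
    return ReleaseKineticsParams(mode="vehicle")


def gaussian_spot_image(
    shape: tuple[int, int],
    centers: list[tuple[float, float]],
    amplitude: float = 3000.0,
    sigma: float = 1.06,
    background: float = 100.0,
) -> np.ndarray:
    """Noise-free synthetic frame with Gaussian puncta (test helper)."""
    img = np.full(shape, float(background))
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    for r, c in centers:
        img += amplitude * np.exp(-((yy - r) ** 2 + (xx - c) ** 2) / (2 * sigma**2))
    return img
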