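import numpy as np
import pytest

from velinfer import LocalizationErrorModel


@pytest.fixture(scope="session")
def noise_mixture() -> LocalizationErrorModel:
    """The calibrated fixed-cell error mixture (f1=0.57, 23/50 nm)."""
    return LocalizationErrorModel(f1=0.57, sigma1=23.0, sigma2=50.0)


@pytest.fixture(scope="session")
def noise_single() -> LocalizationErrorModel:
    """Degenerate single-component noise, sigma_xy = 1 (unit scale)."""
    return LocalizationErrorModel(f1=1.0, sigma1=1.0, sigma2=1.0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
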