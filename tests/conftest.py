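import numpy as np
import pytest

from punctaprox.distfit import RicianMixtureParams
from punctaprox.image import Image


@pytest.fixture
def two_component_truth() -> RicianMixtureParams:
    """Short/long separation mixture used as the simulation ground truth."""
    return RicianMixtureParams(a1=0.7, mu1=0.034, sigma1=0.010,
                               a2=0.3, mu2=0.169, sigma2=0.040)


@pytest.fixture
def random_params():
    """Factory for random valid mixture parameter sets."""
    def make(rng: np.random.Generator) -> RicianMixtureParams:
        return RicianMixtureParams(
            a1=rng.uniform(0.1, 2.0), mu1=rng.uniform(0.0, 0.1),
            sigma1=rng.uniform(0.005, 0.05),
            a2=rng.uniform(0.1, 2.0), mu2=rng.uniform(0.1, 0.4),
            sigma2=rng.uniform(0.01, 0.1))
    return make


def make_image(raster, pixel_size=0.02, label="") -> Image:
    return Image(raster=np.asarray(raster, dtype=float),
                 pixel_size=pixel_size, channel_label=label)
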