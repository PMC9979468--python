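import numpy as np
import pytest

from fundus_scattering.filterbank import ScatteringConfig, build_filterbanks
from fundus_scattering.phantom import PhantomParams, generate_phantom
from fundus_scattering.preprocessing import ChannelImage, extract_channel, resize_image


def gs_channel(seed: int, params: PhantomParams | None = None,
               label: str = "healthy", size=(300, 300)) -> ChannelImage:
    """One grayscale phantom channel image at the analysis size."""
    params = params or PhantomParams()
    im = generate_phantom(params, label, np.random.default_rng(seed))
    return resize_image(extract_channel(im, "GS"), size)


@pytest.fixture(scope="session")
def phantom_gs() -> ChannelImage:
    return gs_channel(7)


@pytest.fixture(scope="session")
def small_config() -> ScatteringConfig:
    """A fast configuration for transform unit tests (64x64 grid, periodic)."""
    return ScatteringConfig(
        invariance_scale=16, quality_factors=(1, 1),
        image_size=(64, 64), boundary="periodic",
    )


@pytest.fixture(scope="session")
def small_banks(small_config):
    return build_filterbanks(small_config)[:2]
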