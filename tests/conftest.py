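import numpy as np
import pytest

from gist_mvd import ImageSimConfig, generate_vessel_image, make_grid
from gist_mvd.segmentation import VesselMask


@pytest.fixture(scope="session")
def default_grid():
    return make_grid()


@pytest.fixture()
def hotspot_image():
    """60 vessels, 80% of them inside one hot-spot disc at the image center."""
    cfg = ImageSimConfig(
        n_vessels=60,
        hotspot_centers=((128.0, 128.0),),
        hotspot_fraction=0.8,
        noise_sd=10.0,
        seed=11,
    )
    return cfg, *generate_vessel_image(cfg)


def mask_from(arr, um_per_px=1.0):
    """Wrap a plain binary array as a VesselMask for scoring tests."""
    return VesselMask.from_mask(np.asarray(arr, dtype=bool), um_per_px)
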