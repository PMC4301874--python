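import numpy as np
import pytest
from skimage import color as skcolor

from fibroquant.segmentation import RgbImage, SegmentationConfig
from fibroquant.synthetic import SyntheticSpec, generate_image


@pytest.fixture
def cfg():
    return SegmentationConfig()


def lab_to_srgb_uint8(L, a, b):
    """Uniform-colour sRGB pixel for a given Lab triple."""
    lab = np.array([[[L, a, b]]], dtype=np.float64)
    rgb = skcolor.lab2rgb(lab)
    return np.clip(np.rint(rgb * 255.0), 0, 255).astype(np.uint8)[0, 0]


def uniform_image(L, a, b, shape=(16, 16)):
    px = lab_to_srgb_uint8(L, a, b)
    return RgbImage(np.broadcast_to(px, shape + (3,)).copy())


@pytest.fixture(scope="session")
def small_synthetic():
    """One modest synthetic section shared across tests (noise sd 5)."""
    spec = SyntheticSpec(width_px=256, height_px=256, n_fibers=50,
                         target_collagen_fraction=0.10, cnf_rate=0.5,
                         colour_noise_sd=5.0, seed=42)
    img, gt = generate_image(spec)
    return spec, img, gt
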