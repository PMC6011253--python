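import numpy as np
import pytest
from skimage.draw import disk

from mana import SyntheticSpec, generate_image


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def easy_scene():
    """One well-separated synthetic scene with its ground truth."""
    spec = SyntheticSpec(image_size=(512, 512), n_nuclei=100, touching_fraction=0.0, seed=1)
    rgb, annotation, labels = generate_image(spec)
    return spec, rgb, annotation, labels


@pytest.fixture(scope="session")
def touching_scene():
    """A crowded scene where 30% of nuclei are placed as touching pairs."""
    spec = SyntheticSpec(image_size=(512, 512), n_nuclei=100, touching_fraction=0.3, seed=21)
    rgb, annotation, labels = generate_image(spec)
    return spec, rgb, annotation, labels


@pytest.fixture
def two_disc_mask():
    """Two overlapping discs of radius 12 with centers 18 px apart."""
    mask = np.zeros((60, 80), dtype=bool)
    for center in ((30, 30), (30, 48)):
        rr, cc = disk(center, 12, shape=mask.shape)
        mask[rr, cc] = True
    return mask


def make_disc_image(centers, radius=12, value=40, background=220, shape=(200, 200)):
    """Grayscale image of uniform dark discs on a bright background."""
    img = np.full(shape, background, dtype=np.uint8)
    for center in centers:
        rr, cc = disk(center, radius, shape=shape)
        img[rr, cc] = value
    return img
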