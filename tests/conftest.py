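import numpy as np
import pytest

from lesionqr.synthetic import default_image_law, generate_images


@pytest.fixture(scope="session")
def image_data():
    """Small lesion-free synthetic image batch with its exact generating law:
    (images (32,1,16,16), truth mask, GaussianField)."""
    law = default_image_law((1, 16, 16), seed=42)
    return generate_images(law, 32, seed=7)


@pytest.fixture(scope="session")
def rater_data():
    """24 lesioned 32x32 images, each with four identical rater masks:
    (images (24,1,32,32), masks (24,4,32,32))."""
    imgs, masks = [], []
    for i in range(24):
        law = default_image_law((1, 32, 32), seed=100 + i, n_lesions=1)
        im, truth, _ = generate_images(law, 1, seed=1100 + i)
        imgs.append(im[0])
        masks.append(np.stack([truth] * 4))
    return np.array(imgs), np.array(masks)
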