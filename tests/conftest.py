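import numpy as np
import pytest

from gwoscreen.synthetic import FundusParams, generate_dataset


def masks_array(samples):
    return np.stack([np.stack([s.disc_mask, s.cup_mask], axis=-1)
                     for s in samples]).astype(np.float32)


@pytest.fixture(scope="session")
def seg_fixture_64():
    """20 high-contrast synthetic fundus images at 64 px with masks."""
    samples, manifest = generate_dataset(
        FundusParams(image_side=64, disc_radius_range=(0.18, 0.28), seed=0),
        n_per_class=10)
    images = np.stack([s.image for s in samples])
    return images, masks_array(samples), manifest, samples


@pytest.fixture(scope="session")
def seg_fixture_32():
    """10 tiny 32 px images for fast hyperparameter-search smoke tests."""
    samples, manifest = generate_dataset(
        FundusParams(image_side=32, disc_radius_range=(0.2, 0.3), seed=0),
        n_per_class=5)
    images = np.stack([s.image for s in samples])
    return images, masks_array(samples), manifest, samples
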