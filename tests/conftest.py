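import numpy as np
import pytest
from skimage.draw import disk as draw_disk

from nucmorph import segmentation, synthetic


@pytest.fixture(scope="session")
def normal_image():
    """20 normal nuclei, DNA + envelope channels, snr 10."""
    spec = synthetic.ImageSpec(n_nuclei=20, seed=1)
    return synthetic.generate_nucleus_image(spec)


@pytest.fixture(scope="session")
def fragmented_image():
    """30 fragmented nuclei (lobe + thin bridge, bare lobe rim)."""
    spec = synthetic.ImageSpec(
        n_nuclei=30, width=1024, height=1024,
        phenotype_mix={"fragmented": 1.0}, seed=2,
    )
    return synthetic.generate_nucleus_image(spec)


@pytest.fixture(scope="session")
def segmented_normal(normal_image):
    labels, records = segmentation.segment_nuclei(
        normal_image.channels[0], normal_image.pixel_size
    )
    return normal_image, labels, records


@pytest.fixture
def disk_mask():
    """Rasterised disk of radius 50 px."""
    mask = np.zeros((120, 120), bool)
    rr, cc = draw_disk((60, 60), 50)
    mask[rr, cc] = True
    return mask
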