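import numpy as np
import pytest

from mosaiq.imaging import BinaryMask
from mosaiq.synthetic import ColonySpec, generate_colony_image


@pytest.fixture(scope="session")
def mixed_colony():
    """One noise-free well-mixed colony with its ground truth."""
    spec = ColonySpec(seed=7)
    image, truth = generate_colony_image(spec)
    return spec, image, truth


@pytest.fixture()
def disk_mask():
    """Full-disk nuclear mask of radius 200 centered in a 512x512 frame."""
    h = w = 512
    rr, cc = np.ogrid[:h, :w]
    dist = np.hypot(rr - (h - 1) / 2, cc - (w - 1) / 2)
    return BinaryMask(dist <= 200.0, source_channel="blue")
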