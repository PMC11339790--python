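import numpy as np
import pytest

from retiqa import synth


@pytest.fixture(scope="session")
def disk_image():
    """Bright disk (radius 200, center 256,256) on black, 512x512x3."""
    yy, xx = np.ogrid[:512, :512]
    inside = (yy - 256) ** 2 + (xx - 256) ** 2 <= 200 ** 2
    img = np.zeros((512, 512, 3), dtype=np.float32)
    img[inside] = [0.8, 0.5, 0.2]
    return img, inside


@pytest.fixture(scope="session")
def clean_fundus():
    """One defect-free synthetic fundus at 128px with its labels."""
    return synth.make_fundus(7, side=128)


@pytest.fixture(scope="session")
def reduced_extractor():
    from retiqa.sir import SIRExtractor
    return SIRExtractor("reduced", (4, 8, 16), 32, seed=0).eval()
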