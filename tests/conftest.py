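import numpy as np
import pytest

from retmorph import extraction, io, synthetic


@pytest.fixture(scope="session")
def default_scene():
    """Rendered synthetic fundus image + ground truth (fixed seed)."""
    spec = synthetic.default_image_spec(seed=1)
    img, truth = synthetic.generate(spec)
    return img, truth


@pytest.fixture(scope="session")
def segmented_scene(default_scene):
    """Vessel segmentation of the default scene (expensive; shared)."""
    img, truth = default_scene
    red_free = io.to_red_free(img)
    seg = extraction.segment_vessels(red_free.pixels.astype(float))
    return img, truth, seg


def draw_bar(height=60, width=120, bar_width=9, value=200.0):
    """Horizontal bright bar of exact odd width on a zero background."""
    arr = np.zeros((height, width))
    r0 = height // 2 - bar_width // 2
    arr[r0:r0 + bar_width, 8:width - 8] = value
    return arr, height // 2
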