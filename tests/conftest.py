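import numpy as np
import pytest

from spotcoloc import SceneParams, generate_scene


def gaussian_spot_image(shape=(64, 64), centers=((20.0, 30.0),), peak=150.0,
                        sigma=2.0, background=0.0):
    """Noiseless sum-of-Gaussians fixture with exactly known centers."""
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]].astype(np.float64)
    img = np.full(shape, float(background))
    for r0, c0 in centers:
        img += peak * np.exp(-(((rr - r0) ** 2 + (cc - c0) ** 2)
                               / (2.0 * sigma ** 2)))
    return img


@pytest.fixture(scope="session")
def standard_scene():
    """The default synthetic study condition: one seeded scene plus truth."""
    return generate_scene(SceneParams(seed=7))


@pytest.fixture(scope="session")
def scene_params():
    return SceneParams(seed=7)


@pytest.fixture
def spot_image():
    return gaussian_spot_image()
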