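import numpy as np
import pytest

from chipscan.fixtures import ChipSpec, render_chip, render_chip_image


@pytest.fixture(scope="session")
def small_spec() -> ChipSpec:
    """A 2.2 x 2.2 mm chip with a handful of crystals: 3x3 tile grid."""
    return ChipSpec(window_mm=(2.2, 2.2), n_crystals=6, seed=7)


@pytest.fixture(scope="session")
def small_chip(small_spec):
    tiles, truth = render_chip(small_spec)
    return tiles, truth


@pytest.fixture(scope="session")
def small_chip_noiseless():
    spec = ChipSpec(window_mm=(2.2, 2.2), n_crystals=6, noise_sigma=0.0, seed=7)
    tiles, truth = render_chip(spec)
    return spec, tiles, truth


@pytest.fixture(scope="session")
def medium_chip_image():
    """A 4 x 4 mm chip image with 30 crystals, for recognition tests."""
    spec = ChipSpec(window_mm=(4.0, 4.0), n_crystals=30, seed=11)
    img, truth = render_chip_image(spec, apply_noise=True)
    return spec, img, truth


def rect_image(
    shape=(300, 300),
    origin=(100.0, 130.0),
    size=(100.0, 40.0),
    background=0.8,
    interior=0.10,
    edge=0.28,
    edge_width=3,
):
    """An axis-aligned dark rectangle on a bright background (pixel units)."""
    img = np.full(shape, background)
    x0, y0 = origin
    w, h = size
    c0, c1 = int(x0), int(x0 + w)
    r0, r1 = int(y0), int(y0 + h)
    img[r0:r1, c0:c1] -= interior
    img[r0 : r0 + edge_width, c0:c1] -= edge
    img[r1 - edge_width : r1, c0:c1] -= edge
    img[r0:r1, c0 : c0 + edge_width] -= edge
    img[r0:r1, c1 - edge_width : c1] -= edge
    return img
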