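import numpy as np
import pytest

from sparseshape import shapes
from sparseshape.config import RunConfig
from sparseshape.front_end import complex_cells, simple_cells


@pytest.fixture(scope="session")
def config():
    return RunConfig()


@pytest.fixture(scope="session")
def disc60(config):
    return shapes.disc_stimulus(60, config=config)


@pytest.fixture(scope="session")
def disc60_stacks(disc60, config):
    st = simple_cells(disc60, config)
    return st, complex_cells(st)


@pytest.fixture(scope="session")
def edge_image(config):
    img = shapes.StimulusImage(np.zeros((400, 400)), center=(200.0, 200.0))
    img.pixels[:, 200:] = 1.0
    return img


@pytest.fixture(scope="session")
def catalog_bases():
    return shapes.load_default_catalog()


@pytest.fixture(scope="session")
def standard_set(config):
    """The full 366-stimulus standard set (rendered once per session)."""
    return shapes.generate_standard_set(128, config=config)


def boundary_mask(pixels):
    fg = pixels >= 0.5
    interior = (np.roll(fg, 1, 0) & np.roll(fg, -1, 0)
                & np.roll(fg, 1, 1) & np.roll(fg, -1, 1))
    return fg & ~interior
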