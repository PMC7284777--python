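import numpy as np
import pytest

from mesocell.nuclei_graph import ImageGrid
from mesocell.synthetic_data import NucleiLayoutParams, simulate_nuclei_image


@pytest.fixture(scope="session")
def small_field_params() -> NucleiLayoutParams:
    """A reduced field (400 x 300 um, 60 cells) for fast unit tests."""
    return NucleiLayoutParams(
        n_cells=60, field_width=400.0, field_height=300.0, seed=11
    )


@pytest.fixture(scope="session")
def small_nuclei_image(small_field_params):
    img, truth = simulate_nuclei_image(small_field_params)
    return img, truth


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture()
def checkerboard() -> ImageGrid:
    tile = np.array([[1, 0], [0, 1]], dtype=float)
    return ImageGrid(np.tile(tile, (8, 8)), pixel_size=1.0)
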