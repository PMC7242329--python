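import numpy as np
import pytest

from ciliaflow import (
    LatticeState,
    assign_ciliated,
    build_tiling,
    initialize_orientations,
    map_to_lattice,
)


@pytest.fixture(scope="session")
def small_tiling():
    """8x8-element tiling at the default resolution (shared, read-only)."""
    return build_tiling(8, 8, 5)


@pytest.fixture(scope="session")
def random_map(small_tiling):
    """Seeded half-ciliated map with random orientations on the small tiling."""
    return initialize_orientations(assign_ciliated(small_tiling, 0.5, 11), 12)


@pytest.fixture()
def rest_state(small_tiling):
    return LatticeState.rest(small_tiling.grid_shape)


@pytest.fixture(scope="session")
def default_params():
    return map_to_lattice(0.5, 2.0, 0.1)
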