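import numpy as np
import pytest

from surfdice import (
    BinaryMask,
    CT_ANISOTROPIC,
    GridSpacing,
    ISOTROPIC_1MM,
    build_neighborhood_table,
)


@pytest.fixture(scope="session")
def table_1mm():
    return build_neighborhood_table(ISOTROPIC_1MM)


@pytest.fixture(scope="session")
def table_ct():
    return build_neighborhood_table(CT_ANISOTROPIC)


def random_mask(seed: int, shape=(8, 8, 8), p=0.4, spacing=ISOTROPIC_1MM):
    """Seeded random binary mask (no margin guarantees)."""
    rng = np.random.default_rng(seed)
    return BinaryMask(rng.random(shape) < p, spacing)


def single_voxel_mask(position, shape=(12, 12, 12), spacing=ISOTROPIC_1MM):
    grid = np.zeros(shape, dtype=bool)
    grid[position] = True
    return BinaryMask(grid, spacing)
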