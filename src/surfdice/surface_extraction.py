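"""Surface images on the half-shifted raster via a marching-cubes area table.

Approximating a surface integral by counting surface voxels is biased,
especially on anisotropic grids. Instead, surface points are placed on a
raster shifted by half the voxel spacing on every axis, so each raster point
is surrounded by exactly 8 voxels. A binary mask admits only ``2**8 = 256``
possible neighbor constellations; for each one the local surface patch is
triangulated once with marching cubes (vertices at exact edge midpoints,
isolevel 1/2 on binary data) and the resulting triangle area in mm^2 is
stored in a 256-entry look-up table. Converting a mask into a surface image
is then a single vectorised table lookup, which keeps the whole metric
pipeline linear in the number of voxels.

Raster convention: surface raster point ``(i, j, k)`` of the
``(n1+1, n2+1, n3+1)`` grid sits at world position
``((i - 1/2)*d1, (j - 1/2)*d2, (k - 1/2)*d3)`` and is surrounded by voxels
``(i-1..i, j-1..j, k-1..k)``. Voxels outside the volume are background, so
every foreground component has a closed, measurable surface.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
from skimage.measure import marching_cubes, mesh_surface_area

from .grid_masks import BinaryMask, GridSpacing, SpacingMismatchError

__all__ = [
    "NeighborhoodTable",
    "SurfaceImage",
    "build_neighborhood_table",
    "extract_surface",
    "total_area",
    "constellation_block",
]

# Bit b = 4*a + 2*b' + c of a constellation code encodes the voxel at local
# offset (a, b', c) within the 2x2x2 block, a,b',c in {0, 1}.
_BIT_WEIGHTS = np.array(
    [[[1, 2], [4, 8]], [[16, 32], [64, 128]]], dtype=np.int64
)


def constellation_block(code: int) -> np.ndarray:
    """The 2x2x2 binary voxel block encoded by a constellation code (0-255)."""
    if not 0 <= code <= 255:
        raise ValueError(f"constellation code must be in [0, 255], got {code}")
    block = np.zeros((2, 2, 2), dtype=np.uint8)
    for a, b, c in product(range(2), repeat=3):
        block[a, b, c] = (code >> (4 * a + 2 * b + c)) & 1
    return block


def constellation_code(block: np.ndarray) -> int:
    """Inverse of :func:`constellation_block`."""
    block = np.asarray(block)
    if block.shape != (2, 2, 2):
        raise ValueError(f"block must have shape (2, 2, 2), got {block.shape}")
    return int(np.sum((block != 0) * _BIT_WEIGHTS))


@dataclass(frozen=True)
class NeighborhoodTable:
    """Constellation code (0-255) -> local marching-cubes surface area (mm^2).

    Entries 0 (all background) and 255 (all foreground) are zero: a uniform
    neighborhood carries no surface.
    """

    spacing: GridSpacing
    areas: np.ndarray

    def __post_init__(self) -> None:
        areas = np.asarray(self.areas, dtype=float)
        if areas.shape != (256,):
            raise ValueError(f"need exactly 256 areas, got shape {areas.shape}")
        if not np.all(np.isfinite(areas)) or np.any(areas < 0):
            raise ValueError("areas must be finite and nonnegative")
        if areas[0] != 0 or areas[255] != 0:
            raise ValueError("uniform constellations (0, 255) must have zero area")
        areas = areas.copy()
        areas.setflags(write=False)
        object.__setattr__(self, "areas", areas)


def _block_area(block: np.ndarray, spacing: GridSpacing) -> float:
    """Marching-cubes triangle area of one 2x2x2 binary block, in mm^2.

    Isolevel 1/2 on {0,1} data places every triangle vertex exactly at an
    edge midpoint; no gradient interpolation is involved.
    """
    if block.min() == block.max():
        return 0.0
    verts, faces, _, _ = marching_cubes(
        block.astype(np.float64),
        level=0.5,
        spacing=(spacing.d1, spacing.d2, spacing.d3),
    )
    # verts come back float32; accumulate triangle areas in float64
    return float(mesh_surface_area(verts.astype(np.float64), faces))


def build_neighborhood_table(spacing: GridSpacing) -> NeighborhoodTable:
    """Triangulate all 256 neighbor constellations and tabulate their areas.

    The triangulation follows one fixed, published marching-cubes case table
    (scikit-image's Lewiner implementation), which resolves the ambiguous
    diagonal constellations deterministically; the resulting 256 areas are
    frozen by a checksum in the test suite.
    """
    areas = np.zeros(256, dtype=float)
    for code in range(1, 255):
        areas[code] = _block_area(constellation_block(code), spacing)
    return NeighborhoodTable(spacing=spacing, areas=areas)


@dataclass(frozen=True)
class SurfaceImage:
    """Per-point local surface area (mm^2) on the half-shifted raster.

    The grid has shape ``(n1+1, n2+1, n3+1)`` for a mask of shape
    ``(n1, n2, n3)``; entries are zero wherever the 8-voxel neighborhood is
    uniform, and the sum of all entries is the total surface area |S|.
    """

    grid: np.ndarray
    spacing: GridSpacing

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=float)
        if grid.ndim != 3:
            raise ValueError(f"surface image must be 3D, got {grid.ndim}D")
        if np.any(grid < 0) or not np.all(np.isfinite(grid)):
            raise ValueError("surface areas must be finite and nonnegative")
        object.__setattr__(self, "grid", grid)

    @property
    def total_area(self) -> float:
        return float(self.grid.sum())

    @property
    def is_empty(self) -> bool:
        return not np.any(self.grid > 0)


def extract_surface(mask: BinaryMask, table: NeighborhoodTable) -> SurfaceImage:
    """Convert a binary mask into its surface image by table lookup.

    Raster point ``(i, j, k)`` receives ``table.areas[code]`` where ``code``
    encodes its 8 neighboring voxels; voxels outside the volume count as
    background, closing surfaces at the volume border.

    Raises
    ------
    SpacingMismatchError
        If the table was built for a different spacing than the mask's.
    """
    if not table.spacing.isclose(mask.spacing):
        raise SpacingMismatchError(
            f"table spacing {table.spacing} does not match mask spacing "
            f"{mask.spacing}"
        )
    n1, n2, n3 = mask.shape
    padded = np.pad(mask.grid.astype(np.uint8), 1, constant_values=0)
    codes = np.zeros((n1 + 1, n2 + 1, n3 + 1), dtype=np.uint8)
    for a, b, c in product(range(2), repeat=3):
        weighted = padded[a : a + n1 + 1, b : b + n2 + 1, c : c + n3 + 1] << (
            4 * a + 2 * b + c
        )
        codes |= weighted
    return SurfaceImage(grid=table.areas[codes], spacing=mask.spacing)


def total_area(surface: SurfaceImage) -> float:
    """Total surface area |S| in mm^2: the sum of all surface-image entries."""
    return surface.total_area
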