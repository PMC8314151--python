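"""Deterministic synthetic phantoms with analytically known properties.

Every input the test suite and the examples need is generated here:
digitized spheres, cuboids, full-width slabs, arrangements of disjoint
congruent cubes, sparse slice labelings, and seeded perturbations. These
phantoms emulate the geometry of clinical organ masks (compact components on
an isotropic or CT-like anisotropic grid) but none of their anatomy or
imaging noise; what they buy is exact knowledge of counts, component
separations and surface structure, so metric behaviour can be checked
against closed-form expectations.

The default grid is 64^3 at 1 mm isotropic spacing; the CT-like variant
uses (0.976, 0.976, 2.5) mm to exercise the anisotropic code paths.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .grid_masks import BinaryMask, GridSpacing, LabeledRegion

__all__ = [
    "ISOTROPIC_1MM",
    "CT_ANISOTROPIC",
    "PhantomSpec",
    "make_phantom",
    "make_multi_cube_pair",
    "make_sparse_labeling",
    "perturb_mask",
]

ISOTROPIC_1MM = GridSpacing(1.0, 1.0, 1.0)
#: Standard head-and-neck planning-CT voxel geometry.
CT_ANISOTROPIC = GridSpacing(0.976, 0.976, 2.5)


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic mask.

    kind : {"sphere", "cuboid", "slab"}
        sphere: voxel centers strictly inside ``radius_mm`` of ``center_vox``
        (world units) are foreground. cuboid: axis-aligned block of
        ``size_vox`` voxels at ``origin_vox``. slab: full-cross-section slab
        of ``thickness_vox`` slices starting at ``start_vox`` along ``axis``.
    """

    kind: str
    grid_shape: tuple[int, int, int] = (64, 64, 64)
    spacing: GridSpacing = ISOTROPIC_1MM
    center_vox: tuple[float, float, float] | None = None
    radius_mm: float | None = None
    origin_vox: tuple[int, int, int] | None = None
    size_vox: tuple[int, int, int] | None = None
    axis: int = 2
    start_vox: int | None = None
    thickness_vox: int | None = None
    border_touching: bool = False


def _check_margin(grid: np.ndarray, border_touching: bool) -> None:
    if border_touching:
        return
    border = np.zeros(grid.shape, dtype=bool)
    for ax in range(3):
        sl = [slice(None)] * 3
        for edge in (0, -1):
            sl[ax] = edge
            border[tuple(sl)] = True
    if np.any(grid & border):
        raise ValueError("phantom foreground touches the grid border")


def make_phantom(spec: PhantomSpec) -> BinaryMask:
    """Generate the mask described by a :class:`PhantomSpec`.

    Deterministic: the same spec always yields the identical mask.
    """
    shape = tuple(spec.grid_shape)
    if spec.kind == "sphere":
        if spec.radius_mm is None:
            raise ValueError("sphere requires radius_mm")
        center = spec.center_vox or tuple((n - 1) / 2 for n in shape)
        coords = np.meshgrid(
            *(np.arange(n, dtype=float) for n in shape), indexing="ij"
        )
        d = spec.spacing.as_array()
        sq = sum(
            ((coords[ax] - center[ax]) * d[ax]) ** 2 for ax in range(3)
        )
        grid = sq < spec.radius_mm**2  # strictly inside
    elif spec.kind == "cuboid":
        if spec.origin_vox is None or spec.size_vox is None:
            raise ValueError("cuboid requires origin_vox and size_vox")
        o, s = spec.origin_vox, spec.size_vox
        if any(o[i] < 0 or o[i] + s[i] > shape[i] for i in range(3)):
            raise ValueError("cuboid exceeds the grid")
        grid = np.zeros(shape, dtype=bool)
        grid[o[0] : o[0] + s[0], o[1] : o[1] + s[1], o[2] : o[2] + s[2]] = True
    elif spec.kind == "slab":
        if spec.start_vox is None or spec.thickness_vox is None:
            raise ValueError("slab requires start_vox and thickness_vox")
        if spec.start_vox < 0 or spec.start_vox + spec.thickness_vox > shape[spec.axis]:
            raise ValueError("slab exceeds the grid")
        grid = np.zeros(shape, dtype=bool)
        sl = [slice(None)] * 3
        sl[spec.axis] = slice(spec.start_vox, spec.start_vox + spec.thickness_vox)
        grid[tuple(sl)] = True
    else:
        raise ValueError(f"unknown phantom kind {spec.kind!r}")
    _check_margin(grid, spec.border_touching or spec.kind == "slab")
    return BinaryMask(grid, spec.spacing)


def make_multi_cube_pair(
    n_cubes: int = 20,
    displaced: int = 1,
    gap_mm: float = 10.0,
    displacement_mm: float = 50.0,
    cube_size_vox: int = 4,
    spacing: GridSpacing = ISOTROPIC_1MM,
) -> tuple[BinaryMask, BinaryMask]:
    """Two masks of ``n_cubes`` congruent disjoint cubes, differing only in
    ``displaced`` cubes translated ``displacement_mm`` away.

    Because the cubes are congruent and separated by more than any intended
    tolerance, the surface DSC at a tolerance below ``gap_mm`` equals
    ``(n_cubes - displaced) / n_cubes`` exactly: matched cubes contribute
    their full surface area on both sides, displaced ones none.

    Constraints: ``displacement_mm`` must exceed the cube's physical
    diagonal plus the gap (so a displaced cube is far from everything), and
    only an isotropic-in-plane layout on a shared grid is generated.
    """
    if not 0 <= displaced <= n_cubes:
        raise ValueError("displaced must be in [0, n_cubes]")
    d = spacing.as_array()
    cube_diag = float(np.sqrt(np.sum((cube_size_vox * d) ** 2)))
    if displacement_mm <= gap_mm + cube_diag:
        raise ValueError(
            "displacement must exceed gap + cube diagonal to keep displaced "
            "cubes isolated"
        )
    gap_vox = [int(np.ceil(gap_mm / d[ax])) for ax in range(3)]
    disp_vox0 = int(np.ceil(displacement_mm / d[0]))
    ny = int(np.ceil(np.sqrt(n_cubes)))
    nz = int(np.ceil(n_cubes / ny))
    pitch_y = cube_size_vox + gap_vox[1]
    pitch_z = cube_size_vox + gap_vox[2]
    margin = 2
    shape = (
        margin + cube_size_vox + disp_vox0 + cube_size_vox + margin,
        margin + ny * cube_size_vox + (ny - 1) * gap_vox[1] + margin,
        margin + nz * cube_size_vox + (nz - 1) * gap_vox[2] + margin,
    )
    grid_a = np.zeros(shape, dtype=bool)
    grid_b = np.zeros(shape, dtype=bool)
    c = cube_size_vox
    for idx in range(n_cubes):
        iy, iz = idx % ny, idx // ny
        y0 = margin + iy * pitch_y
        z0 = margin + iz * pitch_z
        x0 = margin
        grid_a[x0 : x0 + c, y0 : y0 + c, z0 : z0 + c] = True
        if idx < displaced:
            xb = x0 + disp_vox0
            grid_b[xb : xb + c, y0 : y0 + c, z0 : z0 + c] = True
        else:
            grid_b[x0 : x0 + c, y0 : y0 + c, z0 : z0 + c] = True
    return BinaryMask(grid_a, spacing), BinaryMask(grid_b, spacing)


def make_sparse_labeling(
    mask: BinaryMask, slice_indices: Sequence[int], axis: int = 2
) -> tuple[BinaryMask, LabeledRegion]:
    """Restrict a dense mask to a sparse slice labeling.

    Returns the reference restricted to the listed slices along ``axis``
    (others cleared) and the labeled region covering exactly those full
    slices.

    Raises
    ------
    ValueError
        On an empty index list or indices outside the axis extent.
    """
    indices = sorted(set(int(i) for i in slice_indices))
    if not indices:
        raise ValueError("slice_indices must be nonempty")
    extent = mask.shape[axis]
    if indices[0] < 0 or indices[-1] >= extent:
        raise ValueError(
            f"slice indices must lie in [0, {extent}), got {indices[0]}..{indices[-1]}"
        )
    labeled = np.zeros(mask.shape, dtype=bool)
    sl = [slice(None)] * 3
    for i in indices:
        sl[axis] = i
        labeled[tuple(sl)] = True
    sparse_ref = BinaryMask(mask.grid & labeled, mask.spacing)
    return sparse_ref, LabeledRegion(labeled)


def perturb_mask(
    mask: BinaryMask,
    seed: int,
    flip_fraction: float = 0.001,
    shift_vox: tuple[int, int, int] = (0, 0, 0),
) -> BinaryMask:
    """Seeded perturbation: whole-voxel shift plus random voxel flips.

    The shift wraps nothing — it requires the foreground to stay in bounds.
    Flips are sampled uniformly over interior voxels with an explicit
    :class:`numpy.random.Generator` seed; no global random state is touched.
    """
    rng = np.random.default_rng(seed)
    grid = mask.grid
    if any(shift_vox):
        fg = np.argwhere(grid)
        if len(fg):
            lo = fg.min(axis=0) + np.array(shift_vox)
            hi = fg.max(axis=0) + np.array(shift_vox)
            if np.any(lo < 0) or np.any(hi >= np.array(grid.shape)):
                raise ValueError("shift moves foreground out of bounds")
        grid = np.roll(grid, shift_vox, axis=(0, 1, 2))
    grid = grid.copy()
    n_flip = int(round(flip_fraction * grid.size))
    if n_flip:
        idx = [
            rng.integers(1, n - 1, size=n_flip) for n in grid.shape
        ]  # interior only, keeps the border background
        grid[tuple(idx)] = ~grid[tuple(idx)]
    return BinaryMask(grid, mask.spacing)
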