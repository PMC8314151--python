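"""Euclidean distance maps on anisotropic rasters and tolerance rounding.

The border-region membership test of the surface metric ("is this surface
element within tolerance of the other surface?") is realised by an exact
Euclidean distance transform: every raster point receives its physical
distance in mm to the nearest raster point carrying nonzero surface area.
Chamfer approximations are deliberately avoided — their error would leak
directly into the acceptance band.

Because surface points live on a discrete raster, only a discrete set

    D = { sqrt((i*d1)^2 + (j*d2)^2 + (k*d3)^2) : i, j, k >= 0 integers }

of distances can occur between them. Tolerances are therefore rounded to the
nearest element of D before thresholding, so that a nominal tolerance that
falls between two achievable distances behaves identically to the achievable
one it is closest to.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .grid_masks import GridSpacing
from .surface_extraction import SurfaceImage

__all__ = [
    "DistanceMap",
    "AchievableDistanceSet",
    "EmptySurfaceError",
    "distance_map",
    "achievable_distances",
    "round_tolerance",
]

# Relative slack when comparing floating-point raster distances; far below
# any physically meaningful tolerance difference.
_REL_EPS = 1e-9


class EmptySurfaceError(ValueError):
    """A distance map was requested from a surface with no nonzero points."""


@dataclass(frozen=True)
class DistanceMap:
    """Distance (mm) from each raster point to the nearest surface point.

    Same raster as the source :class:`SurfaceImage`; entries at nonzero
    surface points are 0, and values at adjacent raster points differ by at
    most the physical step length (1-Lipschitz).
    """

    grid: np.ndarray
    spacing: GridSpacing


def distance_map(surface: SurfaceImage) -> DistanceMap:
    """Exact anisotropic Euclidean distance transform of a surface image.

    Sources are exactly the raster points with strictly positive area.

    Raises
    ------
    EmptySurfaceError
        If the surface image has no nonzero point; the caller decides the
        metric convention for empty surfaces.
    """
    if surface.is_empty:
        raise EmptySurfaceError("surface image has no nonzero points")
    dist = ndimage.distance_transform_edt(
        surface.grid <= 0,
        sampling=(surface.spacing.d1, surface.spacing.d2, surface.spacing.d3),
    )
    return DistanceMap(grid=np.asarray(dist, dtype=float), spacing=surface.spacing)


@dataclass(frozen=True)
class AchievableDistanceSet:
    """The sorted, deduplicated achievable raster distances up to a maximum."""

    values: np.ndarray
    spacing: GridSpacing
    max_distance: float

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.size == 0 or values[0] != 0:
            raise ValueError("achievable distance set must contain 0")
        if np.any(np.diff(values) <= 0):
            raise ValueError("achievable distances must be strictly increasing")
        values = values.copy()
        values.setflags(write=False)
        object.__setattr__(self, "values", values)

    @property
    def max_value(self) -> float:
        return float(self.values[-1])

    def __len__(self) -> int:
        return len(self.values)


def achievable_distances(
    spacing: GridSpacing, max_distance: float
) -> AchievableDistanceSet:
    """Enumerate all inter-raster-point distances up to ``max_distance``.

    Distances are ``sqrt((i*d1)^2 + (j*d2)^2 + (k*d3)^2)`` over nonnegative
    integer offsets. The bound is inclusive (up to floating-point slack).
    """
    if max_distance < 0:
        raise ValueError(f"max_distance must be >= 0, got {max_distance}")
    bound = max_distance * (1 + _REL_EPS)
    ii = np.arange(int(bound // spacing.d1) + 1) * spacing.d1
    jj = np.arange(int(bound // spacing.d2) + 1) * spacing.d2
    kk = np.arange(int(bound // spacing.d3) + 1) * spacing.d3
    sq = (
        (ii**2)[:, None, None]
        + (jj**2)[None, :, None]
        + (kk**2)[None, None, :]
    )
    dists = np.sqrt(sq[sq <= bound**2])
    values = np.unique(dists)
    return AchievableDistanceSet(
        values=values, spacing=spacing, max_distance=float(max_distance)
    )


def round_tolerance(tau: float, dset: AchievableDistanceSet) -> float:
    """Round a tolerance to the nearest achievable raster distance.

    Ties (``tau`` exactly midway between two achievable distances) resolve
    to the smaller element, which never enlarges the acceptance band. The
    operation is idempotent.

    Raises
    ------
    ValueError
        If ``tau`` is negative or exceeds the enumeration bound of ``dset``.
    """
    if tau < 0:
        raise ValueError(f"tolerance must be >= 0, got {tau}")
    if tau > dset.max_value * (1 + _REL_EPS) and tau > dset.max_distance:
        raise ValueError(
            f"tolerance {tau} exceeds the enumerated bound "
            f"{dset.max_value} of the achievable distance set"
        )
    values = dset.values
    idx = int(np.searchsorted(values, tau))
    if idx == 0:
        return float(values[0])
    if idx >= len(values):
        return float(values[-1])
    below, above = values[idx - 1], values[idx]
    # <= : exact midpoint resolves to the smaller element.
    if tau - below <= above - tau:
        return float(below)
    return float(above)
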