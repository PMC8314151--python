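"""Voxel-grid data model: binary masks with physical spacing.

A segmentation mask lives on a regular 3D raster with (possibly anisotropic)
voxel spacing ``(d1, d2, d3)`` in millimetres, aligned positionally with the
array axes ``(axis0, axis1, axis2)``. The world coordinate of the voxel with
index ``(i, j, k)`` is ``(i*d1, j*d2, k*d3)``. Orientation handling for files
from other sources is confined to :mod:`surfdice.io`; everything in this
module works in that canonical index space.

Pairwise metrics require both masks to share shape and spacing; there is no
implicit resampling (resampling changes the metric, so mismatches fail
loudly via :func:`assert_comparable`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "GridSpacing",
    "BinaryMask",
    "LabeledRegion",
    "OrganTaxonomy",
    "DEFAULT_TAXONOMY",
    "GridMismatchError",
    "ShapeMismatchError",
    "SpacingMismatchError",
    "foreground_count",
    "extract_label",
    "assert_comparable",
    "complement",
]


class GridMismatchError(ValueError):
    """Two masks do not live on the same voxel grid."""


class ShapeMismatchError(GridMismatchError):
    """Masks have different array shapes."""


class SpacingMismatchError(GridMismatchError):
    """Masks have different physical voxel spacings."""


@dataclass(frozen=True)
class GridSpacing:
    """Physical voxel spacing in mm along each array axis.

    Parameters
    ----------
    d1, d2, d3 : float
        Strictly positive, finite edge lengths of one voxel in mm along
        array axes 0, 1 and 2.
    """

    d1: float
    d2: float
    d3: float

    def __post_init__(self) -> None:
        for name, value in (("d1", self.d1), ("d2", self.d2), ("d3", self.d3)):
            if not np.isfinite(value) or value <= 0:
                raise ValueError(
                    f"spacing component {name}={value!r} must be strictly "
                    "positive and finite"
                )

    @classmethod
    def from_sequence(cls, values: Sequence[float]) -> "GridSpacing":
        if len(values) != 3:
            raise ValueError(f"expected 3 spacing components, got {len(values)}")
        return cls(float(values[0]), float(values[1]), float(values[2]))

    def as_array(self) -> np.ndarray:
        return np.array([self.d1, self.d2, self.d3], dtype=float)

    @property
    def voxel_volume(self) -> float:
        """Volume of a single voxel in mm^3."""
        return self.d1 * self.d2 * self.d3

    @property
    def voxel_diagonal(self) -> float:
        """Length of the voxel body diagonal in mm."""
        return float(np.sqrt(self.d1**2 + self.d2**2 + self.d3**2))

    def isclose(self, other: "GridSpacing", rel_tol: float = 1e-6) -> bool:
        return bool(
            np.allclose(self.as_array(), other.as_array(), rtol=rel_tol, atol=0.0)
        )


def _as_bool_grid(grid: np.ndarray) -> np.ndarray:
    arr = np.asarray(grid)
    if arr.ndim != 3:
        raise ValueError(f"mask grid must be 3D, got {arr.ndim}D")
    if any(n < 1 for n in arr.shape):
        raise ValueError(f"mask grid must have all dimensions >= 1, got {arr.shape}")
    # Foreground is "value != 0" for numeric input; bool arrays pass through.
    if arr.dtype != bool:
        arr = arr != 0
    return np.ascontiguousarray(arr)


@dataclass(frozen=True)
class BinaryMask:
    """A binary segmentation mask on a spaced voxel grid.

    Attributes
    ----------
    grid : numpy.ndarray of bool, shape (n1, n2, n3)
        Foreground/background flags. Any numeric array is accepted and
        binarised by ``value != 0``.
    spacing : GridSpacing
        Physical voxel spacing in mm.
    """

    grid: np.ndarray
    spacing: GridSpacing

    def __post_init__(self) -> None:
        object.__setattr__(self, "grid", _as_bool_grid(self.grid))
        if not isinstance(self.spacing, GridSpacing):
            object.__setattr__(
                self, "spacing", GridSpacing.from_sequence(self.spacing)
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape  # type: ignore[return-value]

    @property
    def n_voxels(self) -> int:
        """Total number of voxels N = n1*n2*n3."""
        return int(self.grid.size)

    @property
    def foreground_count(self) -> int:
        return int(np.count_nonzero(self.grid))

    @property
    def volume_mm3(self) -> float:
        """Physical foreground volume: voxel count times voxel volume."""
        return self.foreground_count * self.spacing.voxel_volume

    @property
    def is_empty(self) -> bool:
        return self.foreground_count == 0

    def complement(self) -> "BinaryMask":
        return BinaryMask(~self.grid, self.spacing)


@dataclass(frozen=True)
class LabeledRegion:
    """Flags marking which voxels of an aligned grid carry a reference label.

    Used for sparse ground truth, where only a subset of slices of a scan
    was annotated: metrics restrict counting to the labeled region.
    """

    grid: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "grid", _as_bool_grid(self.grid))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape  # type: ignore[return-value]

    @property
    def labeled_count(self) -> int:
        return int(np.count_nonzero(self.grid))


#: The 21 head-and-neck organ-at-risk structures of the default taxonomy.
_DEFAULT_ORGAN_NAMES: tuple[str, ...] = (
    "Brain",
    "Brainstem",
    "Cochlea-left",
    "Cochlea-right",
    "Lacrimal-left",
    "Lacrimal-right",
    "Lens-left",
    "Lens-right",
    "Lung-left",
    "Lung-right",
    "Mandible",
    "Optic-nerve-left",
    "Optic-nerve-right",
    "Orbit-left",
    "Orbit-right",
    "Parotid-left",
    "Parotid-right",
    "Spinal-canal",
    "Spinal-cord",
    "Submandibular-left",
    "Submandibular-right",
)


@dataclass(frozen=True)
class OrganTaxonomy:
    """An ordered set of organ names, optionally with integer label codes."""

    names: tuple[str, ...] = _DEFAULT_ORGAN_NAMES
    labels: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "names", tuple(self.names))
        if len(set(self.names)) != len(self.names):
            raise ValueError("organ names must be unique")
        if self.labels is not None:
            object.__setattr__(self, "labels", tuple(int(x) for x in self.labels))
            if len(self.labels) != len(self.names):
                raise ValueError("labels and names must have equal length")
            if len(set(self.labels)) != len(self.labels):
                raise ValueError("label codes must be unique")

    def __len__(self) -> int:
        return len(self.names)

    def __contains__(self, name: object) -> bool:
        return name in self.names

    def __iter__(self):
        return iter(self.names)

    def label_for(self, name: str) -> int:
        if self.labels is None:
            raise ValueError("taxonomy has no label codes")
        return self.labels[self.names.index(name)]


DEFAULT_TAXONOMY = OrganTaxonomy()


def foreground_count(mask: BinaryMask) -> int:
    """Number of foreground voxels |M| of a mask.

    The physical volume follows as ``count * d1 * d2 * d3``.
    """
    return mask.foreground_count


def complement(mask: BinaryMask) -> BinaryMask:
    """Mask with foreground and background exchanged."""
    return mask.complement()


def extract_label(
    volume: np.ndarray, spacing: GridSpacing | Sequence[float], label: int
) -> BinaryMask:
    """Binary mask of the voxels of an integer-labeled volume equal to ``label``.

    Parameters
    ----------
    volume : numpy.ndarray, shape (n1, n2, n3)
        Integer label volume (0 = background by convention).
    spacing : GridSpacing or sequence of 3 floats
        Voxel spacing, preserved on the output mask.
    label : int
        The label value to extract.

    Raises
    ------
    ValueError
        If the volume is not an integer array (or integral floats).
    """
    arr = np.asarray(volume)
    if arr.ndim != 3:
        raise ValueError(f"label volume must be 3D, got {arr.ndim}D")
    if not np.issubdtype(arr.dtype, np.integer):
        if np.issubdtype(arr.dtype, np.floating) and np.all(arr == np.round(arr)):
            arr = arr.astype(np.int64)
        else:
            raise ValueError("label volume must contain integer labels")
    if not isinstance(spacing, GridSpacing):
        spacing = GridSpacing.from_sequence(spacing)
    return BinaryMask(arr == int(label), spacing)


def extract_all_labels(
    volume: np.ndarray,
    spacing: GridSpacing | Sequence[float],
    label_map: Mapping[int, str],
) -> dict[str, BinaryMask]:
    """Split a labeled volume into one binary mask per named label."""
    return {
        name: extract_label(volume, spacing, label)
        for label, name in label_map.items()
    }


def assert_comparable(a: BinaryMask, b: BinaryMask, rel_tol: float = 1e-6) -> None:
    """Verify two masks share a voxel grid, else raise a specific error.

    Raises
    ------
    ShapeMismatchError
        If array shapes differ.
    SpacingMismatchError
        If spacings differ by more than relative ``rel_tol``.
    """
    if a.shape != b.shape:
        raise ShapeMismatchError(
            f"mask shapes differ: {a.shape} vs {b.shape}; masks must share a "
            "grid (no implicit resampling)"
        )
    if not a.spacing.isclose(b.spacing, rel_tol=rel_tol):
        raise SpacingMismatchError(
            f"mask spacings differ: {a.spacing} vs {b.spacing}; masks must "
            "share a grid (no implicit resampling)"
        )
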