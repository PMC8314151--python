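"""NIfTI mask I/O and JSON configuration files.

Masks are exchanged as NIfTI volumes (.nii / .nii.gz). On load, volumes are
reoriented to the closest RAS-canonical orientation using the header's
affine, so comparisons always happen in one axis convention regardless of
how the file was stored; spacing comes from the header voxel dimensions.
Label maps (integer label -> organ name) and tolerance sets are plain JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np

from .grid_masks import (
    BinaryMask,
    DEFAULT_TAXONOMY,
    GridSpacing,
    OrganTaxonomy,
    extract_label,
)

__all__ = [
    "LabelMapConfig",
    "read_mask",
    "read_labeled_volume",
    "write_mask",
    "read_label_map",
]


@dataclass(frozen=True)
class LabelMapConfig:
    """Integer label -> organ name mapping loaded from a JSON config."""

    labels: dict[int, str]
    source: str = "<memory>"

    def __post_init__(self) -> None:
        names = list(self.labels.values())
        if len(set(names)) != len(names):
            raise ValueError("organ names in a label map must be unique")

    def validate_against(self, taxonomy: OrganTaxonomy = DEFAULT_TAXONOMY) -> None:
        unknown = sorted(set(self.labels.values()) - set(taxonomy.names))
        if unknown:
            raise ValueError(
                f"label map names not in the taxonomy: {', '.join(unknown)}"
            )

    def items(self):
        return self.labels.items()


def read_label_map(path: str | Path) -> LabelMapConfig:
    """Load a JSON label map ``{"<int label>": "<organ name>", ...}``."""
    payload = json.loads(Path(path).read_text())
    labels = {int(k): str(v) for k, v in payload.items()}
    return LabelMapConfig(labels=labels, source=str(path))


def _load_canonical(path: str | Path) -> tuple[np.ndarray, GridSpacing]:
    img = nib.load(str(path))
    if len(img.shape) != 3:
        raise ValueError(
            f"{path}: expected a 3D volume, got shape {tuple(img.shape)}"
        )
    img = nib.as_closest_canonical(img)
    zooms = img.header.get_zooms()[:3]
    if any(not np.isfinite(z) or z <= 0 for z in zooms):
        raise ValueError(f"{path}: header voxel spacing {zooms} is invalid")
    data = np.asanyarray(img.dataobj)
    return np.asarray(data), GridSpacing.from_sequence(zooms)


def read_mask(path: str | Path, label: int | None = None) -> BinaryMask:
    """Read a NIfTI volume as a binary mask.

    With ``label=None`` any nonzero voxel is foreground; with an integer
    label, only voxels equal to it (the volume must then be integer-valued).
    """
    data, spacing = _load_canonical(path)
    if label is None:
        return BinaryMask(data != 0, spacing)
    return extract_label(data, spacing, label)


def read_labeled_volume(path: str | Path) -> tuple[np.ndarray, GridSpacing]:
    """Read an integer-labeled NIfTI volume and its spacing."""
    data, spacing = _load_canonical(path)
    if not np.issubdtype(data.dtype, np.integer):
        if not np.all(data == np.round(data)):
            raise ValueError(f"{path}: labeled volume must be integer-valued")
        data = data.astype(np.int32)
    return data, spacing


def write_mask(path: str | Path, mask: BinaryMask) -> None:
    """Write a binary mask as NIfTI with a diagonal (spacing) affine."""
    affine = np.diag([mask.spacing.d1, mask.spacing.d2, mask.spacing.d3, 1.0])
    img = nib.Nifti1Image(mask.grid.astype(np.uint8), affine)
    img.header.set_zooms((mask.spacing.d1, mask.spacing.d2, mask.spacing.d3))
    nib.save(img, str(path))


def read_masks_by_label_map(
    path: str | Path, label_map: LabelMapConfig
) -> dict[str, BinaryMask]:
    """Split a labeled NIfTI volume into per-organ binary masks."""
    data, spacing = read_labeled_volume(path)
    return {
        name: extract_label(data, spacing, lab) for lab, name in label_map.items()
    }
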