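"""Organ-specific tolerance calibration from inter-observer contours.

The tolerance τ of the surface metric encodes how far two expert contours of
the same organ typically deviate from each other: deviations within τ should
not be penalised, because equally qualified observers disagree by that much.
Calibration therefore measures, for every pair of observers on every
calibration scan, the bidirectional distances between their surfaces
(weighting each surface element by its area), pools these samples per organ
and takes an area-weighted upper percentile (95th by default) as τ.

Calibration data and evaluation data must be disjoint; the manifest roles of
the cohort layer enforce this separation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .distance_engine import distance_map
from .grid_masks import BinaryMask, assert_comparable
from .surface_extraction import NeighborhoodTable, extract_surface

__all__ = [
    "DistanceSample",
    "ToleranceSet",
    "pairwise_surface_distances",
    "calibrate_tolerances",
    "weighted_percentile",
]


@dataclass(frozen=True)
class DistanceSample:
    """Paired (distance mm, surface-element area mm^2) arrays for one comparison."""

    distances: np.ndarray
    areas: np.ndarray

    def __post_init__(self) -> None:
        distances = np.asarray(self.distances, dtype=float)
        areas = np.asarray(self.areas, dtype=float)
        if distances.shape != areas.shape or distances.ndim != 1:
            raise ValueError("distances and areas must be equal-length 1D arrays")
        if np.any(distances < 0):
            raise ValueError("distances must be nonnegative")
        if np.any(areas <= 0):
            raise ValueError("areas must be strictly positive")
        object.__setattr__(self, "distances", distances)
        object.__setattr__(self, "areas", areas)

    def __len__(self) -> int:
        return len(self.distances)


@dataclass(frozen=True)
class ToleranceSet:
    """Organ name -> tolerance τ (mm), with calibration provenance."""

    tolerances: dict[str, float]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for organ, tau in self.tolerances.items():
            if tau < 0 or not np.isfinite(tau):
                raise ValueError(f"tolerance for {organ!r} must be finite and >= 0")

    def __getitem__(self, organ: str) -> float:
        return self.tolerances[organ]

    def __contains__(self, organ: str) -> bool:
        return organ in self.tolerances

    def to_json(self, path: str | Path) -> None:
        payload: dict = {organ: tau for organ, tau in self.tolerances.items()}
        payload["_provenance"] = self.provenance
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "ToleranceSet":
        payload = json.loads(Path(path).read_text())
        provenance = payload.pop("_provenance", {})
        return cls(
            tolerances={str(k): float(v) for k, v in payload.items()},
            provenance=provenance,
        )


def pairwise_surface_distances(
    a: BinaryMask, b: BinaryMask, table: NeighborhoodTable
) -> DistanceSample:
    """Bidirectional area-weighted surface distances between two contours.

    For every surface element of ``a`` the distance to ``b``'s surface is
    recorded together with the element's area, and vice versa, yielding a
    symmetric sample of the disagreement between the two delineations.

    Raises
    ------
    ValueError
        If either mask is empty (no surface to measure).
    """
    assert_comparable(a, b)
    if a.is_empty or b.is_empty:
        raise ValueError("both masks must be nonempty to sample surface distances")
    surf_a = extract_surface(a, table)
    surf_b = extract_surface(b, table)
    dist_to_a = distance_map(surf_a)
    dist_to_b = distance_map(surf_b)
    nz_a = surf_a.grid > 0
    nz_b = surf_b.grid > 0
    distances = np.concatenate([dist_to_b.grid[nz_a], dist_to_a.grid[nz_b]])
    areas = np.concatenate([surf_a.grid[nz_a], surf_b.grid[nz_b]])
    return DistanceSample(distances=distances, areas=areas)


def weighted_percentile(
    distances: np.ndarray, weights: np.ndarray, percentile: float
) -> float:
    """Area-weighted percentile of a distance sample.

    Returns the smallest distance whose cumulative weight reaches
    ``percentile`` percent of the total weight (the "lower" convention at
    exact cumulative boundaries), which makes the statistic deterministic
    and never larger than necessary.
    """
    if not 0 < percentile <= 100:
        raise ValueError(f"percentile must be in (0, 100], got {percentile}")
    order = np.argsort(distances, kind="stable")
    d_sorted = np.asarray(distances, dtype=float)[order]
    w_sorted = np.asarray(weights, dtype=float)[order]
    cum = np.cumsum(w_sorted)
    total = cum[-1]
    target = (percentile / 100.0) * total
    # tiny slack so an exact boundary (e.g. 95% of area at distance 0 with
    # percentile 95) resolves to the lower distance
    idx = int(np.searchsorted(cum, target * (1 - 1e-12), side="left"))
    idx = min(idx, len(d_sorted) - 1)
    return float(d_sorted[idx])


def calibrate_tolerances(
    samples: Mapping[str, Sequence[DistanceSample]],
    percentile: float = 95.0,
) -> ToleranceSet:
    """Derive per-organ tolerances from pooled inter-observer distance samples.

    For each organ all samples (observer pairs x calibration scans) are
    pooled before the area-weighted percentile is taken, so every surface
    element contributes in proportion to its area regardless of which scan
    it came from.

    Parameters
    ----------
    samples : mapping organ -> sequence of DistanceSample
        Output of :func:`pairwise_surface_distances` per observer pair/scan.
    percentile : float in (0, 100]
        Upper percentile of the pooled area-weighted distance distribution.

    Raises
    ------
    ValueError
        Naming any organ that has no samples.
    """
    empty = sorted(organ for organ, s in samples.items() if len(s) == 0)
    if empty:
        raise ValueError(f"no distance samples for organ(s): {', '.join(empty)}")
    tolerances: dict[str, float] = {}
    n_samples: dict[str, int] = {}
    for organ, organ_samples in samples.items():
        distances = np.concatenate([s.distances for s in organ_samples])
        areas = np.concatenate([s.areas for s in organ_samples])
        tolerances[organ] = weighted_percentile(distances, areas, percentile)
        n_samples[organ] = len(organ_samples)
    provenance = {
        "percentile": float(percentile),
        "n_samples_per_organ": n_samples,
        "statistic": "area-weighted percentile of pooled bidirectional "
        "surface distances",
    }
    return ToleranceSet(tolerances=tolerances, provenance=provenance)
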