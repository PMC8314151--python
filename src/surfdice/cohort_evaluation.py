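"""Cohort-level scoring and per-organ summary statistics.

Scores per-organ predictions against a reference across a cohort of cases
and reduces the resulting records to the per-organ box statistics used in
clinical reporting: median, quartiles, 1.5*IQR whiskers with outliers,
a notch (95% CI of the median) and, for paired comparisons between two
roles (e.g. model vs reference and human observer vs reference), the
per-pair score differences classified against a +/-5 percentage-point band
of non-substantial difference.

Undefined metric values (both masks empty) are excluded from every summary
and counted separately — silent zeros would distort medians.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .grid_masks import BinaryMask
from .overlap_metrics import surface_dsc, volumetric_dsc
from .surface_extraction import NeighborhoodTable, build_neighborhood_table
from .tolerance_calibration import ToleranceSet

__all__ = [
    "ComparisonRecord",
    "OrganSummary",
    "evaluate_case",
    "summarize",
    "records_to_frame",
    "summaries_to_frame",
]

#: Band of per-pair score differences considered non-substantial, in
#: percentage points.
NONSUBSTANTIAL_BAND_PP = 5.0

RECORD_COLUMNS = [
    "case_id",
    "organ",
    "role",
    "surface_dsc",
    "tolerance_used_mm",
    "volumetric_dsc",
    "surface_defined",
    "volumetric_defined",
]

SUMMARY_COLUMNS = [
    "organ",
    "n",
    "n_undefined",
    "median",
    "q1",
    "q3",
    "whisker_low",
    "whisker_high",
    "n_outliers",
    "notch_halfwidth",
    "n_pairs",
    "n_unpaired",
    "mean_diff_pp",
    "n_within_band",
]


@dataclass(frozen=True)
class ComparisonRecord:
    """Metrics of one (case, organ, role) comparison against the reference."""

    case_id: str
    organ: str
    role: str
    surface_dsc: float
    tolerance_used_mm: float
    volumetric_dsc: float

    @property
    def surface_defined(self) -> bool:
        return not math.isnan(self.surface_dsc)

    @property
    def volumetric_defined(self) -> bool:
        return not math.isnan(self.volumetric_dsc)


@dataclass(frozen=True)
class OrganSummary:
    """Box-plot statistics of one organ's scores, plus paired differences."""

    organ: str
    n: int
    n_undefined: int
    median: float = float("nan")
    q1: float = float("nan")
    q3: float = float("nan")
    whisker_low: float = float("nan")
    whisker_high: float = float("nan")
    outliers: tuple[float, ...] = ()
    notch_halfwidth: float = float("nan")
    n_pairs: int = 0
    n_unpaired: int = 0
    mean_diff_pp: float = float("nan")
    n_within_band: int = 0

    @property
    def empty(self) -> bool:
        return self.n == 0


def _empty_like(reference: Mapping[str, BinaryMask]) -> BinaryMask:
    any_mask = next(iter(reference.values()))
    return BinaryMask(np.zeros(any_mask.shape, dtype=bool), any_mask.spacing)


def evaluate_case(
    pred: Mapping[str, BinaryMask],
    truth: Mapping[str, BinaryMask],
    tolerances: ToleranceSet,
    case_id: str = "case",
    role: str = "model",
    table: NeighborhoodTable | None = None,
) -> list[ComparisonRecord]:
    """Score one case's per-organ predictions against the reference.

    Organs present in only one of the two mappings are compared against an
    empty mask of the same geometry, so a missed or hallucinated structure
    scores 0 rather than disappearing from the report; an organ absent from
    both propagates undefined flags.

    Raises
    ------
    KeyError
        If an evaluated organ has no tolerance.
    """
    organs = sorted(set(pred) | set(truth))
    if not organs:
        return []
    missing = [o for o in organs if o not in tolerances]
    if missing:
        raise KeyError(
            f"no tolerance configured for organ(s): {', '.join(missing)}"
        )
    geometry_source = pred if pred else truth
    empty = _empty_like(geometry_source)
    if table is None:
        table = build_neighborhood_table(empty.spacing)
    records = []
    for organ in organs:
        p = pred.get(organ, empty)
        t = truth.get(organ, empty)
        res = surface_dsc(p, t, tolerances[organ], table=table)
        records.append(
            ComparisonRecord(
                case_id=case_id,
                organ=organ,
                role=role,
                surface_dsc=res.value,
                tolerance_used_mm=res.tolerance_used,
                volumetric_dsc=volumetric_dsc(p, t),
            )
        )
    return records


def _box_stats(values: np.ndarray) -> dict:
    """Quartiles (linear interpolation), 1.5*IQR whiskers, outliers, notch."""
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = values[(values >= lo_fence) & (values <= hi_fence)]
    outliers = values[(values < lo_fence) | (values > hi_fence)]
    return {
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "whisker_low": float(inside.min()),
        "whisker_high": float(inside.max()),
        "outliers": tuple(float(v) for v in np.sort(outliers)),
        "notch_halfwidth": float(1.57 * iqr / np.sqrt(len(values))),
    }


def summarize(
    records: Sequence[ComparisonRecord],
    role: str = "model",
    pair_with: str | None = None,
    metric: str = "surface_dsc",
) -> list[OrganSummary]:
    """Per-organ summary of one role's scores, optionally paired with another.

    Parameters
    ----------
    records : sequence of ComparisonRecord
        Records of all roles; the summary covers those with ``record.role
        == role``.
    role : str
        Role to summarise (e.g. ``"model"``).
    pair_with : str, optional
        Comparator role. Differences ``role - pair_with`` are formed per
        (case_id, organ) pair, reported as the mean in percentage points
        and counted against the +/-5 pp non-substantial band. Records
        without a partner are excluded from the difference statistics and
        tallied as unpaired.
    metric : {"surface_dsc", "volumetric_dsc"}
        Which score to summarise.

    Raises
    ------
    ValueError
        If ``records`` is empty or ``metric`` unknown.
    """
    if not records:
        raise ValueError("no records to summarize")
    if metric not in ("surface_dsc", "volumetric_dsc"):
        raise ValueError(f"unknown metric {metric!r}")

    def score(r: ComparisonRecord) -> float:
        return getattr(r, metric)

    organs = sorted({r.organ for r in records})
    primary = [r for r in records if r.role == role]
    comparator = {
        (r.case_id, r.organ): score(r)
        for r in records
        if pair_with is not None and r.role == pair_with
    }

    summaries = []
    for organ in organs:
        organ_records = [r for r in primary if r.organ == organ]
        values = np.array(
            [score(r) for r in organ_records if not math.isnan(score(r))]
        )
        n_undefined = len(organ_records) - len(values)
        if len(values) == 0:
            summaries.append(
                OrganSummary(organ=organ, n=0, n_undefined=n_undefined)
            )
            continue
        stats = _box_stats(values)
        pair_stats: dict = {}
        if pair_with is not None:
            diffs = []
            n_unpaired = 0
            for r in organ_records:
                other = comparator.get((r.case_id, r.organ))
                if (
                    other is None
                    or math.isnan(other)
                    or math.isnan(score(r))
                ):
                    n_unpaired += 1
                    continue
                diffs.append(100.0 * (score(r) - other))
            pair_stats = {
                "n_pairs": len(diffs),
                "n_unpaired": n_unpaired,
                "mean_diff_pp": float(np.mean(diffs)) if diffs else float("nan"),
                "n_within_band": int(
                    sum(abs(d) <= NONSUBSTANTIAL_BAND_PP for d in diffs)
                ),
            }
        summaries.append(
            OrganSummary(
                organ=organ,
                n=len(values),
                n_undefined=n_undefined,
                **stats,
                **pair_stats,
            )
        )
    return summaries


def records_to_frame(records: Sequence[ComparisonRecord]) -> pd.DataFrame:
    """Records as a DataFrame with the documented fixed column order."""
    rows = [
        {
            "case_id": r.case_id,
            "organ": r.organ,
            "role": r.role,
            "surface_dsc": r.surface_dsc,
            "tolerance_used_mm": r.tolerance_used_mm,
            "volumetric_dsc": r.volumetric_dsc,
            "surface_defined": r.surface_defined,
            "volumetric_defined": r.volumetric_defined,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


def summaries_to_frame(summaries: Sequence[OrganSummary]) -> pd.DataFrame:
    """Summaries as a DataFrame with the documented fixed column order."""
    rows = [
        {
            "organ": s.organ,
            "n": s.n,
            "n_undefined": s.n_undefined,
            "median": s.median,
            "q1": s.q1,
            "q3": s.q3,
            "whisker_low": s.whisker_low,
            "whisker_high": s.whisker_high,
            "n_outliers": len(s.outliers),
            "notch_halfwidth": s.notch_halfwidth,
            "n_pairs": s.n_pairs,
            "n_unpaired": s.n_unpaired,
            "mean_diff_pp": s.mean_diff_pp,
            "n_within_band": s.n_within_band,
        }
        for s in summaries
    ]
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)
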