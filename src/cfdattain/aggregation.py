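"""Surface-area-weighted aggregation of segment deficits into subgroups.

Subgroup deficit for window w:

    AD_J(w) = sum_{j in J, AD_j present} AD_j(w) * A_j  /  sum A_j

where A_j is the segment's surface area (constant over time and designated
use).  Segments with no deficit in a window are excluded from numerator and
denominator alike — exclusion, not imputation, keeps the aggregate unbiased
by coverage gaps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .assessment import SpatialUnit
from .errors import InvalidInputError

logger = logging.getLogger(__name__)

SUBGROUP_KINDS = ("designated_use", "salinity_zone", "tidal_system", "total")


@dataclass(frozen=True)
class Subgroup:
    """A named collection of spatial units aggregated together."""

    key_kind: str
    key_value: str
    members: tuple[SpatialUnit, ...]

    def __post_init__(self) -> None:
        if self.key_kind not in SUBGROUP_KINDS:
            raise InvalidInputError(f"unknown subgroup kind {self.key_kind!r}")
        if not self.members:
            raise InvalidInputError(
                f"subgroup {self.key_kind}={self.key_value} has no members"
            )


def build_subgroups(units: list[SpatialUnit]) -> list[Subgroup]:
    """One subgroup per distinct designated use, salinity zone, and tidal
    system, plus a single "total" subgroup over all units.

    Units with a blank key value go to an "unclassified" subgroup for that
    kind and are logged.
    """
    groups: list[Subgroup] = []
    for kind in ("designated_use", "salinity_zone", "tidal_system"):
        buckets: dict[str, list[SpatialUnit]] = {}
        for u in units:
            value = getattr(u, kind) or "unclassified"
            if value == "unclassified":
                logger.warning(
                    "unit %s/%s has blank %s; assigned to 'unclassified'",
                    u.segment_id,
                    u.designated_use,
                    kind,
                )
            buckets.setdefault(value, []).append(u)
        for value in sorted(buckets):
            groups.append(Subgroup(kind, value, tuple(buckets[value])))
    groups.append(Subgroup("total", "TOTAL", tuple(units)))
    return groups


def aggregate_deficit(
    window_results: pd.DataFrame, subgroup: Subgroup
) -> tuple[float, int, float] | None:
    """Area-weighted mean deficit over a subgroup for one window.

    ``window_results`` holds rows for a single window with columns
    segment_id, designated_use, deficit_percent, status.  Each (segment, use)
    member is weighted by its segment's surface area; the "total" subgroup
    therefore weights every designated use of a segment by the same area.
    Returns (aggregate_deficit, n_included, total_area_included), or None
    when no member has data.
    """
    indexed = window_results.set_index(["segment_id", "designated_use"])
    deficits, areas = [], []
    for u in subgroup.members:
        if u.surface_area <= 0:
            raise InvalidInputError(
                f"non-positive area for segment {u.segment_id}"
            )
        key = (u.segment_id, u.designated_use)
        if key not in indexed.index:
            continue
        row = indexed.loc[key]
        if isinstance(row, pd.DataFrame):  # defensive: duplicate rows
            row = row.iloc[0]
        if row["status"] != "ok" or pd.isna(row["deficit_percent"]):
            continue
        deficits.append(float(row["deficit_percent"]))
        areas.append(u.surface_area)
    if not deficits:
        return None
    d = np.asarray(deficits)
    a = np.asarray(areas)
    return float(np.sum(d * a) / np.sum(a)), len(deficits), float(np.sum(a))


def aggregate_series(
    deficits: pd.DataFrame, subgroups: list[Subgroup]
) -> pd.DataFrame:
    """Aggregate every subgroup across every window present in ``deficits``.

    Long-format output: key_kind, key_value, window, aggregate_deficit,
    n_included, total_area_km2; windows with no member data carry NaN.
    """
    rows = []
    for window, wdf in deficits.groupby("window", sort=True):
        for sg in subgroups:
            agg = aggregate_deficit(wdf, sg)
            if agg is None:
                value, n_inc, area = np.nan, 0, 0.0
            else:
                value, n_inc, area = agg
            rows.append(
                {
                    "key_kind": sg.key_kind,
                    "key_value": sg.key_value,
                    "window": window,
                    "aggregate_deficit": value,
                    "n_included": n_inc,
                    "total_area_km2": area,
                }
            )
    out = pd.DataFrame(
        rows,
        columns=[
            "key_kind",
            "key_value",
            "window",
            "aggregate_deficit",
            "n_included",
            "total_area_km2",
        ],
    )
    return out.sort_values(["key_kind", "key_value", "window"]).reset_index(drop=True)
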