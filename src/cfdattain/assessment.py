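"""Per-unit assessment over running 3-year windows.

Each spatial unit (segment x designated use) is scored once per running
3-year assessment window: summer records falling in the window's years are
grouped into sampling events (one calendar date = one event), converted to
per-event spatial exceedances, ranked into a CFD attainment curve, and scored
against the reference curve.  Units with too few events in a window yield a
missing marker rather than a value, so that aggregation can exclude them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import cfd
from .cfd import DEFAULT_MIN_EVENTS, ReferenceCurve
from .errors import ConfigurationError, InvalidInputError
from .exceedance import (
    DESIGNATED_USES,
    SUMMER_MONTHS,
    CriterionSpec,
)

logger = logging.getLogger(__name__)

SALINITY_ZONES = ("TF", "OH", "MH", "PH")


@dataclass(frozen=True)
class AssessmentWindow:
    """A running 3-year assessment period, e.g. 1985-1987."""

    start_year: int

    @property
    def end_year(self) -> int:
        return self.start_year + 2

    @property
    def label(self) -> str:
        return f"{self.start_year}-{self.end_year}"

    @property
    def years(self) -> tuple[int, int, int]:
        return (self.start_year, self.start_year + 1, self.start_year + 2)


@dataclass(frozen=True)
class SpatialUnit:
    """A segment x designated-use pair with its aggregation metadata."""

    segment_id: str
    designated_use: str
    surface_area: float
    salinity_zone: str
    tidal_system: str

    def __post_init__(self) -> None:
        if self.surface_area <= 0:
            raise InvalidInputError(
                f"surface_area must be > 0, got {self.surface_area} "
                f"for {self.segment_id}"
            )
        if self.salinity_zone not in SALINITY_ZONES:
            raise InvalidInputError(
                f"salinity_zone must be one of {SALINITY_ZONES}, "
                f"got {self.salinity_zone!r}"
            )
        if self.designated_use not in DESIGNATED_USES:
            raise InvalidInputError(
                f"designated_use must be one of {DESIGNATED_USES}, "
                f"got {self.designated_use!r}"
            )


def enumerate_windows(first_year: int, last_year: int) -> list[AssessmentWindow]:
    """All running 3-year windows (y, y+2) with y from first_year on.

    A span of 1985-2016 yields 30 windows, 1985-1987 through 2014-2016;
    2000-2016 yields 15.
    """
    if last_year < first_year + 2:
        raise InvalidInputError(
            f"span {first_year}-{last_year} is shorter than one 3-year window"
        )
    return [AssessmentWindow(y) for y in range(first_year, last_year - 1)]


def assess_unit(
    records: pd.DataFrame,
    window: AssessmentWindow,
    criterion: CriterionSpec,
    reference: ReferenceCurve,
    season: Iterable[int] = SUMMER_MONTHS,
    min_events: int = DEFAULT_MIN_EVENTS,
) -> cfd.DeficitResult | None:
    """Score one unit for one window; None marks insufficient data.

    ``records`` is a monitoring table pre-filtered to a single unit, with
    columns date (datetime64), do_mg_l, weight, segment_id, designated_use.
    Multiple same-day records form one sampling event.
    """
    if records.empty:
        return None
    uses = records["designated_use"].unique()
    segs = records["segment_id"].unique()
    if len(uses) != 1 or len(segs) != 1:
        raise ConfigurationError(
            f"assess_unit expects records for one unit, got segments {segs} "
            f"and uses {uses}"
        )
    if criterion.designated_use != uses[0]:
        raise ConfigurationError(
            f"criterion is for {criterion.designated_use}, unit is {uses[0]}"
        )
    months = frozenset(season)
    dates = records["date"]
    mask = dates.dt.year.isin(window.years) & dates.dt.month.isin(months)
    sub = records.loc[mask]
    if sub["date"].nunique() < min_events:
        return None

    exceedances = []
    for _, grp in sub.groupby("date", sort=True):
        total = grp["weight"].sum()
        if total <= 0:
            continue
        below = grp.loc[grp["do_mg_l"] < criterion.threshold, "weight"].sum()
        exceedances.append(min(100.0, max(0.0, 100.0 * below / total)))
    if len(exceedances) < min_events:
        return None

    curve = cfd.build_attainment_curve(
        exceedances, min_events=min_events, unit_label=f"{segs[0]}/{uses[0]}"
    )
    return cfd.score_curve(curve, reference, segs[0], uses[0], window.label)


def assess_all(
    monitoring: pd.DataFrame,
    units: Sequence[SpatialUnit],
    criteria: Mapping[str, CriterionSpec],
    reference: ReferenceCurve,
    windows: Sequence[AssessmentWindow],
    season: Iterable[int] = SUMMER_MONTHS,
    min_events: int = DEFAULT_MIN_EVENTS,
) -> pd.DataFrame:
    """Score every unit for every window.

    Returns one row per (segment, use, window) in deterministic order, with
    NaN deficit and a reason in ``status`` where data were insufficient —
    missing is a first-class marker, never a silent zero.  Monitoring rows
    referencing unknown units are skipped and counted in the log.
    """
    known = {(u.segment_id, u.designated_use) for u in units}
    if not monitoring.empty:
        keys = list(zip(monitoring["segment_id"], monitoring["designated_use"]))
        unknown_mask = np.array([k not in known for k in keys])
        n_unknown = int(unknown_mask.sum())
        if n_unknown:
            logger.warning(
                "skipping %d monitoring rows for units absent from the unit table",
                n_unknown,
            )
            monitoring = monitoring.loc[~unknown_mask]

    rows = []
    ordered = sorted(units, key=lambda u: (u.segment_id, u.designated_use))
    grouped = (
        dict(tuple(monitoring.groupby(["segment_id", "designated_use"])))
        if not monitoring.empty
        else {}
    )
    for unit in ordered:
        recs = grouped.get((unit.segment_id, unit.designated_use))
        criterion = criteria.get(unit.designated_use)
        if criterion is None:
            raise ConfigurationError(
                f"no criterion configured for designated use {unit.designated_use}"
            )
        for window in windows:
            result = (
                assess_unit(recs, window, criterion, reference, season, min_events)
                if recs is not None
                else None
            )
            if result is None:
                rows.append(
                    {
                        "segment_id": unit.segment_id,
                        "designated_use": unit.designated_use,
                        "window": window.label,
                        "n_events": 0,
                        "deficit_percent": np.nan,
                        "attaining": pd.NA,
                        "status": "missing:insufficient_events",
                    }
                )
            else:
                rows.append(
                    {
                        "segment_id": result.segment_id,
                        "designated_use": result.designated_use,
                        "window": result.window_label,
                        "n_events": result.n_events,
                        "deficit_percent": result.deficit,
                        "attaining": result.attaining,
                        "status": "ok",
                    }
                )
    out = pd.DataFrame(
        rows,
        columns=[
            "segment_id",
            "designated_use",
            "window",
            "n_events",
            "deficit_percent",
            "attaining",
            "status",
        ],
    )
    n_missing = int((out["status"] != "ok").sum()) if not out.empty else 0
    logger.info(
        "assessed %d unit-windows (%d missing)", len(out), n_missing
    )
    return out


def initial_status(
    deficits: pd.DataFrame, segment_id: str, designated_use: str
) -> tuple[str, float] | None:
    """Earliest non-missing window and its deficit for one unit.

    Mirrors the reporting convention for units with no data in the earliest
    windows: their "initial" status is the first window that has data.
    Returns None when the unit never has data.
    """
    sub = deficits[
        (deficits["segment_id"] == segment_id)
        & (deficits["designated_use"] == designated_use)
        & (deficits["status"] == "ok")
    ].sort_values("window")
    if sub.empty:
        return None
    row = sub.iloc[0]
    return row["window"], float(row["deficit_percent"])
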