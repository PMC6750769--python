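"""Per-event spatial criterion exceedance.

One sampling event for a spatial unit (a segment x designated-use pair) is a
set of stations or interpolation cells observed on one calendar date, each
carrying a dissolved-oxygen value and a nonnegative spatial weight (the share
of the unit's area or volume that the record represents).  The event's
*exceedance* is the weighted percent of the unit's space whose DO falls below
the applicable criterion threshold.
"""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .errors import ConsistencyError, InvalidInputError

logger = logging.getLogger(__name__)

#: The three dissolved-oxygen designated uses handled by this package:
#: open water (OW), deep water (DW), deep channel (DC).
DESIGNATED_USES = ("OW", "DW", "DC")

#: Summer assessment season, June through September.
SUMMER_MONTHS = frozenset({6, 7, 8, 9})


@dataclass(frozen=True)
class MonitoringRecord:
    """A single DO measurement with its spatial weight and unit labels.

    Temperature and salinity are accepted for compatibility with field
    monitoring tables but play no role here: records arrive already labeled
    with their vertical layer (the designated use).
    """

    station_or_cell_id: str
    timestamp: _dt.date
    segment_id: str
    designated_use: str
    do_value: float
    weight: float = 1.0
    temperature_c: float | None = None
    salinity_psu: float | None = None

    def __post_init__(self) -> None:
        if self.designated_use not in DESIGNATED_USES:
            raise InvalidInputError(
                f"designated_use must be one of {DESIGNATED_USES}, "
                f"got {self.designated_use!r}"
            )
        if self.do_value < 0:
            raise InvalidInputError(f"do_value must be >= 0, got {self.do_value}")
        if self.weight < 0:
            raise InvalidInputError(f"weight must be >= 0, got {self.weight}")


@dataclass(frozen=True)
class CriterionSpec:
    """A DO criterion: threshold (mg/L) applying to one use in one season."""

    designated_use: str
    threshold: float
    season: frozenset[int] = field(default=SUMMER_MONTHS)

    def __post_init__(self) -> None:
        if self.designated_use not in DESIGNATED_USES:
            raise InvalidInputError(
                f"designated_use must be one of {DESIGNATED_USES}, "
                f"got {self.designated_use!r}"
            )
        if self.threshold <= 0:
            raise InvalidInputError(f"threshold must be > 0, got {self.threshold}")
        if not self.season:
            raise InvalidInputError("season must be a nonempty set of months")
        object.__setattr__(self, "season", frozenset(self.season))


#: Conventional default thresholds (mg/L) for the summer season.  These are
#: placeholders at typical regulatory magnitudes and must be overridden with
#: the jurisdiction's season-specific values for a real assessment.
DEFAULT_CRITERIA = {
    "OW": CriterionSpec("OW", 5.0),
    "DW": CriterionSpec("DW", 3.0),
    "DC": CriterionSpec("DC", 1.0),
}


@dataclass(frozen=True)
class EventExceedance:
    """Percent of a unit's space exceeding the criterion at one event."""

    segment_id: str
    designated_use: str
    timestamp: _dt.date
    exceedance: float
    n_records: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.exceedance <= 100.0:
            raise InvalidInputError(
                f"exceedance must be in [0, 100], got {self.exceedance}"
            )
        if self.n_records < 1:
            raise InvalidInputError("n_records must be >= 1")


def compute_event_exceedance(
    records: Sequence[MonitoringRecord], criterion: CriterionSpec
) -> EventExceedance:
    """Weighted percent of space below the criterion threshold for one event.

    A record exactly at the threshold counts as attaining: criteria are
    minimum requirements, so exceedance is defined by strict ``do < threshold``.

    Parameters
    ----------
    records
        All records for one (segment, use, date); must share those labels and
        have positive total weight.
    criterion
        The threshold to apply; its use must match the records'.

    Raises
    ------
    InvalidInputError
        Empty record list or zero total weight.
    ConsistencyError
        Records mix segments, uses, or dates, or the criterion targets a
        different use.
    """
    if not records:
        raise InvalidInputError("cannot compute exceedance of an empty record list")
    first = records[0]
    for r in records:
        if (
            r.segment_id != first.segment_id
            or r.designated_use != first.designated_use
            or r.timestamp != first.timestamp
        ):
            raise ConsistencyError(
                "records for one event must share segment, use, and date; got "
                f"({r.segment_id}, {r.designated_use}, {r.timestamp}) vs "
                f"({first.segment_id}, {first.designated_use}, {first.timestamp})"
            )
    if criterion.designated_use != first.designated_use:
        raise ConsistencyError(
            f"criterion is for {criterion.designated_use}, "
            f"records are for {first.designated_use}"
        )
    total = sum(r.weight for r in records)
    if total <= 0:
        raise InvalidInputError(
            f"zero total weight for event ({first.segment_id}, "
            f"{first.designated_use}, {first.timestamp})"
        )
    below = sum(r.weight for r in records if r.do_value < criterion.threshold)
    return EventExceedance(
        segment_id=first.segment_id,
        designated_use=first.designated_use,
        timestamp=first.timestamp,
        exceedance=min(100.0, max(0.0, 100.0 * below / total)),  # fp guard
        n_records=len(records),
    )


def filter_season(
    records: Iterable[MonitoringRecord], season: Iterable[int] = SUMMER_MONTHS
) -> list[MonitoringRecord]:
    """Keep records whose calendar month is in ``season``, preserving order."""
    months = frozenset(season)
    if not months:
        raise InvalidInputError("season must be a nonempty set of months")
    return [r for r in records if r.timestamp.month in months]
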