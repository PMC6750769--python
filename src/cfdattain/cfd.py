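"""Attainment curves, reference curves, and the attainment-deficit statistic.

The assessment square is the 100 x 100 percent-time x percent-space plane.
An *attainment curve* is the complementary cumulative step curve of per-event
spatial exceedances: events are sorted by exceedance, descending, along the
time axis at plotting positions i/n, so the area under the curve equals the
arithmetic mean of the event exceedances exactly.  A *reference curve* bounds
the allowable exceedance: the area beneath it is the space-time exceedance
that may occur without ecological degradation.

The *attainment deficit* is the negated area of the region lying under the
attainment curve and above the reference curve (the non-allowable
exceedance), scaled to percent of the assessment square.  It is 0 when the
unit fully attains and -100 in complete non-compliance against a zero-area
reference.

Orientation note: ranking events ascending along time (a conventional CDF)
and descending (the complementary form used here) are mirror images of each
other; every area in this module, and therefore the deficit, is invariant to
the choice.  The descending orientation is fixed so the curve is
non-increasing like the reference curve it is compared with.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import brentq

from .errors import FormatError, InsufficientDataError, InvalidInputError

#: Floating-point guard for the binary attainment decision, in percent of
#: space.  Far below the 0.1-percent reporting precision.
ATTAINMENT_TOLERANCE = 1e-9

#: Minimum number of events required to build a rankable curve.
DEFAULT_MIN_EVENTS = 3


def _segments_from_points(
    x: np.ndarray, y: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Piecewise-linear segments (x0, x1, y0, y1) from vertex arrays."""
    return x[:-1], x[1:], y[:-1], y[1:]


class _PiecewiseCurve:
    """Shared geometry for curves over the assessment square.

    Subclasses provide ``segments()`` returning four arrays (x0, x1, y0, y1);
    the curve is linear on each [x0, x1] and the pieces tile [0, 100].
    """

    def segments(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        raise NotImplementedError

    def area(self) -> float:
        """Area under the curve as percent of the 100 x 100 square."""
        x0, x1, y0, y1 = self.segments()
        return float(np.sum((x1 - x0) * (y0 + y1)) / 2.0 / 100.0)

    def evaluate_on(self, lo: np.ndarray, hi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Curve values at the endpoints of subintervals [lo, hi].

        Each subinterval must lie within a single piece; step discontinuities
        at subinterval endpoints resolve to the piece covering the interior.
        """
        x0, x1, y0, y1 = self.segments()
        mid = (lo + hi) / 2.0
        idx = np.clip(np.searchsorted(x0, mid, side="right") - 1, 0, len(x0) - 1)
        dx = x1[idx] - x0[idx]
        slope = np.where(dx > 0, (y1[idx] - y0[idx]) / np.where(dx > 0, dx, 1.0), 0.0)
        return y0[idx] + (lo - x0[idx]) * slope, y0[idx] + (hi - x0[idx]) * slope

    def breakpoints(self) -> np.ndarray:
        x0, _, _, _ = self.segments()
        return np.append(x0, 100.0)


@dataclass(frozen=True)
class AttainmentCurve(_PiecewiseCurve):
    """CFD step curve of per-event spatial exceedances.

    ``heights`` holds the exceedances sorted descending; step i occupies time
    fractions ((i-1)/n, i/n] x 100 at that height (right-continuous closure
    at (100, last value)).  Tied exceedances stay as separate equal steps —
    area and deficit are invariant to their order.
    """

    heights: tuple[float, ...]

    def __post_init__(self) -> None:
        h = np.asarray(self.heights, dtype=float)
        if h.size == 0:
            raise InvalidInputError("attainment curve needs at least one event")
        if np.any(h < 0) or np.any(h > 100):
            raise InvalidInputError("exceedances must lie in [0, 100]")
        if np.any(np.diff(h) > 0):
            raise InvalidInputError("step heights must be non-increasing")

    @property
    def n_events(self) -> int:
        return len(self.heights)

    @property
    def points(self) -> list[tuple[float, float]]:
        """Vertices (time_fraction, exceedance) at plotting positions i/n."""
        n = self.n_events
        return [(100.0 * (i + 1) / n, h) for i, h in enumerate(self.heights)]

    def segments(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        n = self.n_events
        edges = 100.0 * np.arange(n + 1) / n
        h = np.asarray(self.heights, dtype=float)
        return edges[:-1], edges[1:], h, h


@dataclass(frozen=True)
class ReferenceCurve(_PiecewiseCurve):
    """Piecewise-linear non-increasing boundary of allowable exceedance."""

    x: tuple[float, ...]
    y: tuple[float, ...]

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if x.size < 2:
            raise InvalidInputError("reference curve needs at least two points")
        if x[0] != 0.0 or x[-1] != 100.0:
            raise InvalidInputError("reference curve must span time 0 to 100")
        if np.any(np.diff(x) <= 0):
            raise InvalidInputError("time fractions must be strictly increasing")
        if np.any(y < 0) or np.any(y > 100):
            raise InvalidInputError("space percents must lie in [0, 100]")
        if np.any(np.diff(y) > 1e-12):
            raise InvalidInputError("reference curve must be non-increasing")

    @property
    def points(self) -> list[tuple[float, float]]:
        return list(zip(self.x, self.y))

    @property
    def allowable_area(self) -> float:
        """Percent of the assessment square beneath the curve."""
        return self.area()

    def segments(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        return _segments_from_points(
            np.asarray(self.x, dtype=float), np.asarray(self.y, dtype=float)
        )


def build_attainment_curve(
    exceedances: Sequence[float] | Iterable,
    min_events: int = DEFAULT_MIN_EVENTS,
    unit_label: str = "",
) -> AttainmentCurve:
    """Rank event exceedances into a CFD attainment curve.

    Accepts raw percents or ``EventExceedance`` objects.  Raises
    ``InsufficientDataError`` below ``min_events``: a curve from fewer events
    is not meaningfully rankable.
    """
    values = [
        float(e.exceedance) if hasattr(e, "exceedance") else float(e)
        for e in exceedances
    ]
    if len(values) < min_events:
        where = f" for {unit_label}" if unit_label else ""
        raise InsufficientDataError(
            f"need at least {min_events} events to build a curve{where}, "
            f"got {len(values)}"
        )
    return AttainmentCurve(heights=tuple(sorted(values, reverse=True)))


#: Number of grid intervals used to discretise the hyperbolic reference
#: family into a piecewise-linear curve.  The grid is quadratically graded
#: toward t = 0 where the curvature concentrates.
_HYPERBOLIC_GRID = 2000


def make_hyperbolic_reference(allowable_area: float) -> ReferenceCurve:
    """Convex reference curve y(t) = 100 k / (t + k) with a prescribed area.

    The shape parameter k is calibrated by root-finding so that the
    discretised (piecewise-linear) curve's under-curve area equals
    ``allowable_area`` to well within 0.01 percent of the square.  The
    degenerate areas 0 and 100 return the all-zero and all-100 curves.

    This family is a qualitative stand-in for biologically derived reference
    curves; segment-specific curves should be loaded from file when available.
    """
    if not 0.0 <= allowable_area <= 100.0:
        raise InvalidInputError(
            f"allowable_area must be in [0, 100], got {allowable_area}"
        )
    if allowable_area == 0.0:
        return ReferenceCurve(x=(0.0, 100.0), y=(0.0, 0.0))
    if allowable_area == 100.0:
        return ReferenceCurve(x=(0.0, 100.0), y=(100.0, 100.0))

    grid = 100.0 * (np.arange(_HYPERBOLIC_GRID + 1) / _HYPERBOLIC_GRID) ** 2

    def discretised_area(k: float) -> float:
        y = 100.0 * k / (grid + k)
        return float(np.trapezoid(y, grid) / 100.0)

    # Area is strictly increasing in k: k -> 0 gives 0, k -> inf gives 100.
    k = brentq(
        lambda k: discretised_area(k) - allowable_area, 1e-8, 1e10, xtol=1e-12
    )
    y = np.clip(100.0 * k / (grid + k), 0.0, 100.0)  # fp guard at t = 0
    return ReferenceCurve(x=tuple(grid), y=tuple(y))


def load_reference_curve(
    table: Sequence[tuple[float, float]]
) -> ReferenceCurve:
    """Build a reference curve from (time_percent, space_percent) pairs.

    Rows are sorted by time fraction; non-monotone space values are rejected
    with the offending row identified.  The curve must span 0 to 100 in time.
    """
    rows = sorted((float(t), float(s)) for t, s in table)
    if len(rows) < 2:
        raise FormatError("reference table needs at least two rows")
    for i, (t, s) in enumerate(rows):
        if not (0.0 <= t <= 100.0 and 0.0 <= s <= 100.0):
            raise FormatError(f"row {i}: percents out of [0, 100]: ({t}, {s})")
        if i > 0 and s > rows[i - 1][1]:
            raise FormatError(
                f"row {i}: space percent {s} increases from {rows[i - 1][1]}; "
                "reference curves must be non-increasing"
            )
        if i > 0 and t == rows[i - 1][0]:
            raise FormatError(f"row {i}: duplicate time fraction {t}")
    x, y = zip(*rows)
    return ReferenceCurve(x=x, y=y)


def curve_area(curve: _PiecewiseCurve) -> float:
    """Area under a curve as percent of the assessment square."""
    return curve.area()


def _excess_area(attainment: _PiecewiseCurve, reference: _PiecewiseCurve) -> float:
    """Area (percent of square) where the attainment curve exceeds the reference.

    Exact piecewise geometry: on each merged subinterval both curves are
    linear, so max(0, A - R) integrates in closed form, splitting at the
    crossing where the difference changes sign.
    """
    xs = np.unique(np.concatenate([attainment.breakpoints(), reference.breakpoints()]))
    lo, hi = xs[:-1], xs[1:]
    a0, a1 = attainment.evaluate_on(lo, hi)
    r0, r1 = reference.evaluate_on(lo, hi)
    d0, d1 = a0 - r0, a1 - r1
    width = hi - lo

    both_pos = (d0 >= 0) & (d1 >= 0)
    cross = (d0 > 0) != (d1 > 0)
    area = np.where(both_pos, width * (d0 + d1) / 2.0, 0.0)
    # One endpoint positive: a triangle up to the sign change.
    denom = np.where(cross, np.abs(d0 - d1), 1.0)
    tri = 0.5 * width * np.maximum(d0, d1, where=cross, out=np.zeros_like(d0)) ** 2 / denom
    area = np.where(cross & ~both_pos, tri, area)
    return float(np.sum(area) / 100.0)


def attainment_deficit(
    attainment: _PiecewiseCurve, reference: _PiecewiseCurve
) -> float:
    """Signed attainment deficit, in [-100, 0].

    The non-allowable exceedance — the region under the attainment curve and
    above the reference curve — is measured as a percent of the assessment
    square and negated.  Exactly 0 when the attainment curve never rises
    above the reference; -100 when exceedance is total and nothing is
    allowable.
    """
    return float(np.clip(-_excess_area(attainment, reference), -100.0, 0.0)) + 0.0


def is_attaining(
    attainment: _PiecewiseCurve,
    reference: _PiecewiseCurve,
    tolerance: float = ATTAINMENT_TOLERANCE,
) -> bool:
    """Binary pass/fail: does the attainment curve stay below the reference?

    True iff the attainment curve lies at or below the reference at every
    abscissa, within ``tolerance`` percent of space.  Consistent with the
    deficit: attaining implies |deficit| <= tolerance.
    """
    xs = np.unique(np.concatenate([attainment.breakpoints(), reference.breakpoints()]))
    lo, hi = xs[:-1], xs[1:]
    a0, a1 = attainment.evaluate_on(lo, hi)
    r0, r1 = reference.evaluate_on(lo, hi)
    return bool(np.all(a0 - r0 <= tolerance) and np.all(a1 - r1 <= tolerance))


@dataclass(frozen=True)
class DeficitResult:
    """Attainment deficit for one segment x use x assessment window."""

    segment_id: str
    designated_use: str
    window_label: str
    deficit: float
    n_events: int
    attaining: bool

    def __post_init__(self) -> None:
        if not -100.0 <= self.deficit <= 0.0:
            raise InvalidInputError(
                f"deficit must be in [-100, 0], got {self.deficit}"
            )


def score_curve(
    attainment: AttainmentCurve,
    reference: ReferenceCurve,
    segment_id: str,
    designated_use: str,
    window_label: str,
    tolerance: float = ATTAINMENT_TOLERANCE,
) -> DeficitResult:
    """Deficit plus binary decision for one unit and window."""
    deficit = attainment_deficit(attainment, reference)
    return DeficitResult(
        segment_id=segment_id,
        designated_use=designated_use,
        window_label=window_label,
        deficit=deficit,
        n_events=attainment.n_events,
        attaining=is_attaining(attainment, reference, tolerance),
    )
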