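"""Synthetic monitoring scenarios for end-to-end testing.

Emulates multi-segment summer dissolved-oxygen monitoring: segments spanning
four orders of magnitude in surface area, 12-20 sampling events per summer
per unit, a within-summer seasonal cycle, a linear inter-annual trend, AR(1)
noise shared across a unit's events, and an optional step change.  Every
output is reproducible from the scenario seed.
"""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidInputError

logger = logging.getLogger(__name__)

_SALINITY_ZONES = ("TF", "OH", "MH", "PH")
_N_TIDAL_SYSTEMS = 13


@dataclass(frozen=True)
class ScenarioSpec:
    """Parameters of one synthetic monitoring scenario.

    Defaults mirror typical fixed-station tidal monitoring: 12-20 events per
    summer, segment areas log-uniform over 0.13-1521 km^2, a mild AR(1)
    autocorrelation (phi = 0.3) in the DO noise, and a modest within-summer
    seasonal cycle.
    """

    n_segments: int = 5
    uses: tuple[str, ...] = ("OW", "DW", "DC")
    first_year: int = 1985
    last_year: int = 2016
    events_per_summer: tuple[int, int] = (12, 20)
    do_mean: float = 5.5
    do_trend: float = 0.0  # mg/L per year
    noise_sd: float = 1.0  # stationary sd of the AR(1) noise, mg/L
    ar1_phi: float = 0.3
    seasonal_amplitude: float = 0.8  # mg/L swing across the summer
    change_point: tuple[int, float] | None = None  # (year, shift in mg/L)
    area_range: tuple[float, float] = (0.13, 1521.0)
    n_stations: int = 4  # records per event
    station_sd: float = 0.4  # between-station spread within an event, mg/L
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_segments < 1:
            raise InvalidInputError("n_segments must be >= 1")
        if not self.uses:
            raise InvalidInputError("at least one designated use is required")
        if self.events_per_summer[0] < 1 or (
            self.events_per_summer[1] < self.events_per_summer[0]
        ):
            raise InvalidInputError("events_per_summer must be a valid range")
        if not abs(self.ar1_phi) < 1:
            raise InvalidInputError("|ar1_phi| must be < 1 for stationarity")
        if self.noise_sd < 0 or self.station_sd < 0:
            raise InvalidInputError("noise scales must be nonnegative")
        if self.last_year < self.first_year:
            raise InvalidInputError("last_year must be >= first_year")


def generate_segments(spec: ScenarioSpec) -> pd.DataFrame:
    """Segment/unit metadata table: one row per (segment, designated use).

    Areas are log-uniform over ``spec.area_range`` (one area per segment,
    shared across its uses); salinity zones and tidal systems are assigned
    round-robin so every vocabulary value appears once enough segments exist.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.area_range
    areas = np.exp(rng.uniform(np.log(lo), np.log(hi), size=spec.n_segments))
    rows = []
    for i in range(spec.n_segments):
        seg = f"SEG{i + 1:03d}"
        zone = _SALINITY_ZONES[i % len(_SALINITY_ZONES)]
        system = f"SYS{(i % _N_TIDAL_SYSTEMS) + 1:02d}"
        for use in spec.uses:
            rows.append(
                {
                    "segment_id": seg,
                    "designated_use": use,
                    "surface_area_km2": float(areas[i]),
                    "salinity_zone": zone,
                    "tidal_system": system,
                }
            )
    return pd.DataFrame(rows)


def _ar1(rng: np.random.Generator, n: int, phi: float, sd: float) -> np.ndarray:
    """Stationary AR(1) path with marginal standard deviation ``sd``."""
    if n == 0:
        return np.empty(0)
    if sd == 0:
        return np.zeros(n)
    innov_sd = sd * np.sqrt(1.0 - phi * phi)
    x = np.empty(n)
    x[0] = rng.normal(0.0, sd)
    eps = rng.normal(0.0, innov_sd, size=n - 1)
    for i in range(1, n):
        x[i] = phi * x[i - 1] + eps[i - 1]
    return x


def _summer_dates(rng: np.random.Generator, year: int, n_events: int) -> list[_dt.date]:
    """Distinct sampling dates drawn from June 1 through September 30."""
    start = _dt.date(year, 6, 1).toordinal()
    end = _dt.date(year, 9, 30).toordinal()
    days = rng.choice(np.arange(start, end + 1), size=n_events, replace=False)
    return [_dt.date.fromordinal(int(d)) for d in sorted(days)]


def generate_monitoring_table(
    spec: ScenarioSpec, units: pd.DataFrame
) -> pd.DataFrame:
    """Synthetic monitoring records for every unit and summer.

    Per unit-summer, the event count is uniform over ``events_per_summer``
    and dates are distinct days in June-September.  The unit's event-level DO
    follows mean + trend * (year - first_year) + a sinusoidal within-summer
    cycle + AR(1) noise (continuous across years); the optional change point
    shifts the mean from its year onward.  Each event spawns ``n_stations``
    records with independent station spread and Dirichlet-uniform spatial
    weights.  DO is truncated at the physical floor of 0 mg/L; truncations
    are counted in the log.
    """
    if units.empty:
        raise InvalidInputError("unit table must be nonempty")
    rng = np.random.default_rng(np.random.default_rng(spec.seed).integers(2**31))
    years = range(spec.first_year, spec.last_year + 1)
    rows = []
    n_truncated = 0
    for _, unit in units.iterrows():
        counts = rng.integers(
            spec.events_per_summer[0], spec.events_per_summer[1] + 1, size=len(years)
        )
        noise = _ar1(rng, int(np.sum(counts)), spec.ar1_phi, spec.noise_sd)
        pos = 0
        for year, n_events in zip(years, counts):
            dates = _summer_dates(rng, year, int(n_events))
            base = spec.do_mean + spec.do_trend * (year - spec.first_year)
            if spec.change_point is not None and year >= spec.change_point[0]:
                base += spec.change_point[1]
            for date in dates:
                season_frac = (date.timetuple().tm_yday - 152) / 122.0
                seasonal = -spec.seasonal_amplitude * np.sin(np.pi * season_frac)
                event_do = base + seasonal + noise[pos]
                pos += 1
                weights = rng.dirichlet(np.ones(spec.n_stations))
                spread = rng.normal(0.0, spec.station_sd, size=spec.n_stations)
                for s in range(spec.n_stations):
                    do = event_do + spread[s]
                    if do < 0:
                        do = 0.0
                        n_truncated += 1
                    rows.append(
                        {
                            "station_or_cell_id": f"{unit['segment_id']}-ST{s + 1}",
                            "date": pd.Timestamp(date),
                            "segment_id": unit["segment_id"],
                            "designated_use": unit["designated_use"],
                            "do_mg_l": float(do),
                            "weight": float(weights[s]),
                        }
                    )
    if n_truncated:
        logger.info("truncated %d DO values at the 0 mg/L floor", n_truncated)
    return pd.DataFrame(rows)


def generate_deficit_series(
    n: int,
    slope: float = 0.0,
    ar1_phi: float = 0.3,
    noise_sd: float = 5.0,
    seed: int = 0,
    base: float = -50.0,
) -> np.ndarray:
    """Bounded deficit series: clip(base + slope * t + AR(1), -100, 0).

    Feeds the trend module directly, without going through monitoring data.
    ``slope`` is in percent per window-step.
    """
    if n < 4:
        raise InvalidInputError("deficit series needs n >= 4")
    rng = np.random.default_rng(seed)
    t = np.arange(n, dtype=float)
    series = base + slope * t + _ar1(rng, n, ar1_phi, noise_sd)
    return np.clip(series, -100.0, 0.0)


def inject_change_point(series, index: int, shift: float) -> np.ndarray:
    """Shift values from ``index`` (0-based) onward and re-clip to [-100, 0]."""
    x = np.asarray(series, dtype=float).copy()
    if not 1 <= index < len(x):
        raise InvalidInputError(
            f"change-point index must be in [1, {len(x) - 1}], got {index}"
        )
    x[index:] += shift
    return np.clip(x, -100.0, 0.0)
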