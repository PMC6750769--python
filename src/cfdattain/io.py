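"""Readers, writers, and run configuration for the assessment pipeline."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import cfd
from .assessment import SpatialUnit
from .errors import FormatError, InvalidInputError
from .exceedance import DEFAULT_CRITERIA, DESIGNATED_USES, CriterionSpec

logger = logging.getLogger(__name__)

MONITORING_REQUIRED = (
    "station_or_cell_id",
    "date",
    "segment_id",
    "designated_use",
    "do_mg_l",
)
MONITORING_OPTIONAL = ("weight", "temperature_c", "salinity_psu")

UNITS_REQUIRED = (
    "segment_id",
    "designated_use",
    "surface_area_km2",
    "salinity_zone",
    "tidal_system",
)


@dataclass
class RunConfig:
    """Everything a pipeline run needs, loadable from YAML or JSON."""

    criteria: dict[str, CriterionSpec] = field(
        default_factory=lambda: dict(DEFAULT_CRITERIA)
    )
    reference: str = "hyperbolic:10"  # or a CSV path
    season: tuple[int, ...] = (6, 7, 8, 9)
    min_events: int = cfd.DEFAULT_MIN_EVENTS
    first_year: int = 1985
    last_year: int = 2016
    alpha_levels: tuple[float, ...] = (0.05, 0.1, 0.25)
    subgroup_kinds: tuple[str, ...] = (
        "designated_use",
        "salinity_zone",
        "tidal_system",
        "total",
    )
    lag_policy: str = "significant"
    seed: int = 0
    out_dir: str = "results"

    def __post_init__(self) -> None:
        alphas = tuple(self.alpha_levels)
        if list(alphas) != sorted(alphas) or not all(0 < a < 1 for a in alphas):
            raise InvalidInputError(
                f"alpha levels must be strictly increasing within (0, 1), "
                f"got {alphas}"
            )


def load_config(path: str | Path) -> RunConfig:
    """Load a RunConfig from a YAML or JSON file."""
    path = Path(path)
    text = path.read_text()
    raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise FormatError(f"config file {path} must hold a mapping")
    kwargs = dict(raw)
    if "criteria" in kwargs:
        season = frozenset(kwargs.get("season", (6, 7, 8, 9)))
        kwargs["criteria"] = {
            use: CriterionSpec(use, float(thr), season)
            for use, thr in kwargs["criteria"].items()
        }
    for key in ("season", "alpha_levels", "subgroup_kinds"):
        if key in kwargs:
            kwargs[key] = tuple(kwargs[key])
    return RunConfig(**kwargs)


def resolve_reference(source: str) -> cfd.ReferenceCurve:
    """'hyperbolic:<percent>' or a path to a two-column CSV."""
    if source.startswith("hyperbolic:"):
        return cfd.make_hyperbolic_reference(float(source.split(":", 1)[1]))
    return read_reference_csv(source)


def read_monitoring_csv(path: str | Path) -> pd.DataFrame:
    """Load and validate a monitoring table.

    Malformed rows (unparseable dates, non-numeric or negative DO/weights,
    unknown designated uses) are skipped with their line numbers logged; a
    missing required column is fatal.  A missing weight column defaults to
    equal weights.  Temperature/salinity columns are accepted and ignored.
    """
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in MONITORING_REQUIRED if c not in df.columns]
    if missing:
        raise FormatError(
            f"{path}: missing required column(s): {', '.join(missing)}"
        )
    ignored = [c for c in ("temperature_c", "salinity_psu") if c in df.columns]
    if ignored:
        logger.info(
            "%s: columns %s accepted but unused (records arrive pre-labeled "
            "by layer)",
            path,
            ignored,
        )
    dates = pd.to_datetime(df["date"], format="ISO8601", errors="coerce")
    do = pd.to_numeric(df["do_mg_l"], errors="coerce")
    if "weight" in df.columns:
        weight = pd.to_numeric(df["weight"], errors="coerce")
    else:
        weight = pd.Series(1.0, index=df.index)
        logger.info("%s: no weight column; defaulting to equal weights", path)
    bad = (
        dates.isna()
        | do.isna()
        | (do < 0)
        | weight.isna()
        | (weight < 0)
        | ~df["designated_use"].isin(DESIGNATED_USES)
    )
    if bad.any():
        for idx in df.index[bad]:
            logger.warning("%s: skipping malformed row at line %d", path, idx + 2)
        logger.warning("%s: skipped %d malformed row(s)", path, int(bad.sum()))
    out = pd.DataFrame(
        {
            "station_or_cell_id": df["station_or_cell_id"],
            "date": dates,
            "segment_id": df["segment_id"],
            "designated_use": df["designated_use"],
            "do_mg_l": do,
            "weight": weight,
        }
    ).loc[~bad]
    logger.info("%s: loaded %d records", path, len(out))
    return out.reset_index(drop=True)


def write_monitoring_csv(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def read_units_csv(path: str | Path) -> list[SpatialUnit]:
    """Load segment/unit metadata into SpatialUnit objects."""
    df = pd.read_csv(path)
    missing = [c for c in UNITS_REQUIRED if c not in df.columns]
    if missing:
        raise FormatError(
            f"{path}: missing required column(s): {', '.join(missing)}"
        )
    return units_from_frame(df)


def units_from_frame(df: pd.DataFrame) -> list[SpatialUnit]:
    return [
        SpatialUnit(
            segment_id=str(r.segment_id),
            designated_use=str(r.designated_use),
            surface_area=float(r.surface_area_km2),
            salinity_zone=str(r.salinity_zone),
            tidal_system=str(r.tidal_system),
        )
        for r in df.itertuples()
    ]


def read_reference_csv(path: str | Path) -> cfd.ReferenceCurve:
    """Two-column (time_percent, space_percent) reference-curve table."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: reference curve needs two columns")
    pairs = list(zip(df.iloc[:, 0].astype(float), df.iloc[:, 1].astype(float)))
    return cfd.load_reference_curve(pairs)


def write_reference_csv(curve: cfd.ReferenceCurve, path: str | Path) -> None:
    pd.DataFrame(curve.points, columns=["time_percent", "space_percent"]).to_csv(
        path, index=False
    )
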