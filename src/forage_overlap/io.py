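"""Readers and writers for logger records, fishing sets, geometry and results.

Tabular data travel as pandas DataFrames with documented column schemas
(:data:`FIX_COLUMNS`, :data:`SET_COLUMNS`, :data:`DIVE_COLUMNS`); the 1 Hz
depth trace is held in :class:`SensorSeries`.  All timestamps are stored
timezone-naive in UTC; local time (UTC-4, configurable) is used only for the
daylight GPS cadence and for hour binning.  CSV files are comma-separated
with ISO-8601 timestamps and '.' decimals.
"""

from __future__ import annotations

import datetime as _dt
import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import MultiPolygon, Polygon, mapping, shape

logger = logging.getLogger("forage_overlap")

#: hours to add to UTC to obtain local clock time at the colony
LOCAL_UTC_OFFSET_H = -4

#: GPS fix table schema
FIX_COLUMNS = ["bird_id", "timestamp", "lon", "lat", "source"]
#: fishing set table schema
SET_COLUMNS = ["set_id", "date", "lon", "lat", "species", "season"]
#: dive event table schema (lon/lat NaN when the dive is unlocated)
DIVE_COLUMNS = [
    "bird_id", "start", "end", "duration_s", "max_depth_m", "mean_depth_m", "lon", "lat",
]

AUTUMN_MONTHS = (4, 5, 6, 7)       # April–July
SPRING_MONTHS = (11, 12, 1, 2)     # November–February


class FormatError(ValueError):
    """Malformed input file (missing columns, bad values)."""


class ValidationError(ValueError):
    """Well-formed file whose contents violate an invariant."""


@dataclass
class SensorSeries:
    """A uniform depth/temperature trace for one bird.

    ``depth_m`` is sampled at ``rate_hz`` starting at ``start`` (UTC); gaps in
    the record are NaN samples (flagged, never interpolated).  Depth is
    positive down; slightly negative values are surface-noise and tolerated
    down to -0.5 m.
    """

    bird_id: str
    start: np.datetime64
    depth_m: np.ndarray
    rate_hz: float = 1.0
    temperature_c: np.ndarray | None = None

    def __post_init__(self):
        self.depth_m = np.asarray(self.depth_m, dtype=float)
        self.start = np.datetime64(self.start, "ns")
        finite = self.depth_m[np.isfinite(self.depth_m)]
        if finite.size and finite.min() < -0.5:
            raise ValidationError(
                f"depth below -0.5 m in series for bird {self.bird_id}: {finite.min():.2f}"
            )

    def __len__(self) -> int:
        return self.depth_m.size

    @property
    def n_gaps(self) -> int:
        return int(np.sum(~np.isfinite(self.depth_m)))

    def times(self) -> np.ndarray:
        step = np.timedelta64(int(round(1e9 / self.rate_hz)), "ns")
        return self.start + step * np.arange(self.depth_m.size)


@dataclass
class CoastGeometry:
    """Island, mainland, the 1-nautical-mile exclusion band and the analysis buffer.

    All members are shapely polygons in lon/lat (WGS84).  The exclusion band
    hugs the mainland coast with a width of 1,852 m; the buffer is a 62 km
    disc around the island centroid.
    """

    island: Polygon
    mainland: Polygon
    exclusion_1nm: Polygon | MultiPolygon
    buffer_62km: Polygon
    extras: dict = field(default_factory=dict)

    def __post_init__(self):
        for name in ("island", "mainland", "exclusion_1nm", "buffer_62km"):
            geom = getattr(self, name)
            if not geom.is_valid:
                raise ValidationError(f"coast geometry '{name}' is invalid (self-intersecting?)")
        if not self.buffer_62km.contains(self.island):
            raise ValidationError("analysis buffer must contain the island")


def assign_season(date: _dt.date | pd.Timestamp) -> str | None:
    """Season label from the fishing calendar: autumn = Apr–Jul, spring = Nov–Feb.

    Returns None for dates in the closed (no-fishing) months.
    """
    m = pd.Timestamp(date).month
    if m in AUTUMN_MONTHS:
        return "autumn"
    if m in SPRING_MONTHS:
        return "spring"
    return None


# ---------------------------------------------------------------------------
# Logger CSV

_LOGGER_COLS = ["bird_id", "timestamp", "depth_m", "temp_c", "lon", "lat", "fix_source"]


def write_logger_csv(series_by_bird: dict[str, SensorSeries], fixes: pd.DataFrame, path) -> None:
    """Write per-sample logger rows; rows carrying a GPS fix have lon/lat filled."""
    frames = []
    for bird_id, series in series_by_bird.items():
        df = pd.DataFrame(
            {
                "bird_id": bird_id,
                "timestamp": series.times(),
                "depth_m": series.depth_m,
                "temp_c": (
                    series.temperature_c
                    if series.temperature_c is not None
                    else np.full(len(series), np.nan)
                ),
            }
        )
        sub = fixes[fixes["bird_id"] == bird_id]
        merged = df.merge(
            sub[["timestamp", "lon", "lat", "source"]].rename(columns={"source": "fix_source"}),
            on="timestamp",
            how="left",
        )
        frames.append(merged)
    out = pd.concat(frames, ignore_index=True)[_LOGGER_COLS]
    out.to_csv(path, index=False, date_format="%Y-%m-%dT%H:%M:%S.%f")


def read_logger_csv(path) -> tuple[dict[str, SensorSeries], pd.DataFrame]:
    """Read a logger CSV into per-bird :class:`SensorSeries` and a fix table.

    Missing seconds become NaN (gap) samples.  Non-monotone timestamps raise
    :class:`ValidationError` naming the first offending row; out-of-range
    coordinates raise too.
    """
    df = pd.read_csv(path, low_memory=False)
    missing = {"bird_id", "timestamp", "depth_m"} - set(df.columns)
    if missing:
        raise FormatError(f"logger CSV missing mandatory columns: {sorted(missing)}")
    df["timestamp"] = pd.to_datetime(df["timestamp"])

    series_by_bird: dict[str, SensorSeries] = {}
    fix_rows = []
    for bird_id, sub in df.groupby("bird_id", sort=False):
        ts = sub["timestamp"].to_numpy()
        bad = np.nonzero(np.diff(ts) <= np.timedelta64(0))[0]
        if bad.size:
            row = sub.index[bad[0] + 1]
            raise ValidationError(
                f"non-monotone timestamps for bird {bird_id} at input row {row}"
            )
        step = np.timedelta64(1_000_000_000, "ns")  # logger CSV is 1 Hz
        n = int((ts[-1] - ts[0]) / step) + 1
        depth = np.full(n, np.nan)
        temp = np.full(n, np.nan)
        idx = ((ts - ts[0]) / step).astype(int)
        depth[idx] = sub["depth_m"].to_numpy()
        if "temp_c" in sub:
            temp[idx] = sub["temp_c"].to_numpy()
        series_by_bird[str(bird_id)] = SensorSeries(
            bird_id=str(bird_id), start=ts[0], depth_m=depth, rate_hz=1.0,
            temperature_c=temp if np.isfinite(temp).any() else None,
        )
        if "lon" in sub.columns and "lat" in sub.columns:
            fsub = sub[np.isfinite(sub["lon"]) & np.isfinite(sub["lat"])]
            if len(fsub):
                if (fsub["lat"].abs() > 90).any() or (fsub["lon"].abs() > 180).any():
                    raise ValidationError(
                        f"fix coordinates out of range for bird {bird_id}"
                    )
                fix_rows.append(
                    pd.DataFrame(
                        {
                            "bird_id": str(bird_id),
                            "timestamp": fsub["timestamp"].to_numpy(),
                            "lon": fsub["lon"].to_numpy(),
                            "lat": fsub["lat"].to_numpy(),
                            "source": fsub.get(
                                "fix_source", pd.Series(["unknown"] * len(fsub))
                            ).to_numpy(),
                        }
                    )
                )
    fixes = (
        pd.concat(fix_rows, ignore_index=True)
        if fix_rows
        else pd.DataFrame(columns=FIX_COLUMNS)
    )
    return series_by_bird, fixes


# ---------------------------------------------------------------------------
# Fishing sets


def write_fishing_sets(sets: pd.DataFrame, path) -> None:
    sets.to_csv(path, index=False, columns=["set_id", "date", "lon", "lat", "species"],
                date_format="%Y-%m-%d")


def read_fishing_sets(path) -> pd.DataFrame:
    """Read presence-only purse-seine sets; assign seasons from date windows.

    Rows dated in the closed season (Aug–Oct, Mar) are dropped with a warning;
    unparseable dates raise :class:`FormatError` naming the rows.
    """
    df = pd.read_csv(path)
    missing = {"date", "lon", "lat", "species"} - set(df.columns)
    if missing:
        raise FormatError(f"fishing-set CSV missing columns: {sorted(missing)}")
    dates = pd.to_datetime(df["date"], errors="coerce")
    bad = df.index[dates.isna()].tolist()
    if bad:
        raise FormatError(f"unparseable dates in fishing-set CSV at rows {bad}")
    df = df.copy()
    df["date"] = dates
    if "set_id" not in df.columns:
        df["set_id"] = [f"set{i:04d}" for i in range(len(df))]
    df["season"] = [assign_season(d) for d in df["date"]]
    n_closed = int(df["season"].isna().sum())
    if n_closed:
        warnings.warn(
            f"{n_closed} fishing set(s) dated in the closed season were excluded",
            stacklevel=2,
        )
        df = df[df["season"].notna()]
    if (df["lat"].abs() > 90).any() or (df["lon"].abs() > 180).any():
        raise ValidationError("fishing-set coordinates out of range")
    return df.reset_index(drop=True)[SET_COLUMNS]


# ---------------------------------------------------------------------------
# GeoJSON


def write_isopleths(polygons, path) -> None:
    """Write isopleths as a GeoJSON FeatureCollection (level + areas as properties)."""
    features = []
    for iso in polygons:
        features.append(
            {
                "type": "Feature",
                "geometry": mapping(iso.geometry),
                "properties": {
                    "level": iso.level,
                    "area_km2": iso.area_km2,
                    "pre_erase_area_km2": iso.pre_erase_area_km2,
                },
            }
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_isopleths(path):
    from .homerange import IsoplethPolygon  # local import avoids a cycle

    with open(path) as fh:
        fc = json.load(fh)
    out = []
    for feat in fc.get("features", []):
        props = feat["properties"]
        out.append(
            IsoplethPolygon(
                level=props["level"],
                geometry=shape(feat["geometry"]),
                pre_erase_area_km2=props.get("pre_erase_area_km2", props["area_km2"]),
                area_km2=props["area_km2"],
            )
        )
    return out


def write_coast(coast: CoastGeometry, path) -> None:
    features = []
    for name in ("island", "mainland", "exclusion_1nm", "buffer_62km"):
        features.append(
            {
                "type": "Feature",
                "geometry": mapping(getattr(coast, name)),
                "properties": {"name": name},
            }
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_coast(path) -> CoastGeometry:
    with open(path) as fh:
        fc = json.load(fh)
    parts = {f["properties"]["name"]: shape(f["geometry"]) for f in fc["features"]}
    return CoastGeometry(
        island=parts["island"],
        mainland=parts["mainland"],
        exclusion_1nm=parts["exclusion_1nm"],
        buffer_62km=parts["buffer_62km"],
    )
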