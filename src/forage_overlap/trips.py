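"""Trip segmentation, trip metrics, near-shore exclusion and hourly centroids.

Works on located-dive tables (dive rows with a linked lon/lat).  Trip
delimitation — a gap longer than ``gap_h`` between consecutive located dives
starts a new trip — is a pipeline choice, since dive bouts separated by a
colony visit show up as exactly such gaps; it is exposed as configuration.
Trips shorter than 2 h or with fewer than two located fixes are flagged
excluded rather than dropped.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon

from .geodesy import LocalProjection, geodesic_distance, initial_bearing
from .io import LOCAL_UTC_OFFSET_H

TRIP_COLUMNS = [
    "bird_id", "season", "trip_id", "start", "end", "duration_h", "n_located",
    "max_dist_km", "total_dist_km", "mean_bearing_deg", "excluded", "reason",
]


def circular_mean_deg(bearings_deg) -> float:
    """Circular mean of compass bearings, in [0, 360)."""
    b = np.radians(np.asarray(bearings_deg, dtype=float))
    if b.size == 0:
        raise ValueError("circular mean of an empty set")
    s, c = np.sin(b).mean(), np.cos(b).mean()
    if np.hypot(s, c) < 1e-12:
        raise ValueError("circular mean undefined: bearings perfectly balanced")
    out = float(np.degrees(np.arctan2(s, c)) % 360.0)
    return 0.0 if out >= 360.0 else out  # -0.0 % 360 can round to exactly 360


def filter_nearshore(
    points: pd.DataFrame,
    island: Polygon,
    projection: LocalProjection,
    radius_m: float = 100.0,
) -> pd.DataFrame:
    """Drop rows whose position lies within ``radius_m`` of the island coastline.

    "Within" includes the island interior; the test is a vectorised
    distance-to-polygon against the island in the local projection.
    """
    if len(points) == 0:
        return points
    island_xy = projection.project_geom(island)
    x, y = projection.forward(points["lon"].to_numpy(), points["lat"].to_numpy())
    near = shapely.dwithin(shapely.points(np.column_stack([x, y])), island_xy, radius_m)
    return points[~near].reset_index(drop=True)


def segment_trips(
    located_dives: pd.DataFrame,
    nest_lonlat: tuple[float, float] | None = None,
    gap_h: float = 4.0,
    min_duration_h: float = 2.0,
    min_fixes: int = 2,
) -> pd.DataFrame:
    """Split each bird's located dives into trips at gaps longer than ``gap_h``.

    Returns the dive table with a ``trip_id`` column added (one id per bird
    and trip).  Use :func:`trip_metrics` / :func:`trip_table` afterwards.
    """
    if len(located_dives) == 0:
        out = located_dives.copy()
        out["trip_id"] = pd.Series([], dtype=str)
        return out
    parts = []
    for bird_id, sub in located_dives.groupby("bird_id", sort=False):
        sub = sub.sort_values("start").reset_index(drop=True)
        gaps = (
            sub["start"].iloc[1:].to_numpy() - sub["end"].iloc[:-1].to_numpy()
        ) / np.timedelta64(1, "h")
        trip_no = np.concatenate(([0], np.cumsum(gaps > gap_h)))
        sub = sub.copy()
        sub["trip_id"] = [f"{bird_id}_t{int(i):02d}" for i in trip_no]
        parts.append(sub)
    return pd.concat(parts, ignore_index=True)


def trip_metrics(trip_dives: pd.DataFrame, nest_lonlat: tuple[float, float]) -> dict:
    """Metrics for a single trip: duration, max/total distance, mean bearing.

    Duration runs from the start of the first to the end of the last dive;
    distances are WGS84 geodesics; the bearing is the circular mean of the
    nest-to-fix azimuths.  Requires >= 2 located fixes.
    """
    sub = trip_dives.dropna(subset=["lon", "lat"]).sort_values("start")
    if len(sub) < 2:
        raise ValueError("trip metrics need >= 2 located fixes (trip should be excluded)")
    lon0, lat0 = nest_lonlat
    lons = sub["lon"].to_numpy()
    lats = sub["lat"].to_numpy()
    dists = np.array([geodesic_distance(lon0, lat0, lo, la) for lo, la in zip(lons, lats)])
    legs = np.array(
        [
            geodesic_distance(lons[i], lats[i], lons[i + 1], lats[i + 1])
            for i in range(len(lons) - 1)
        ]
    )
    bearings = [
        initial_bearing(lon0, lat0, lo, la)
        for lo, la in zip(lons, lats)
        if not (lo == lon0 and la == lat0)
    ]
    duration_h = float(
        (sub["end"].iloc[-1] - sub["start"].iloc[0]) / np.timedelta64(1, "h")
    )
    return {
        "start": sub["start"].iloc[0],
        "end": sub["end"].iloc[-1],
        "duration_h": duration_h,
        "n_located": int(len(sub)),
        "max_dist_km": float(dists.max()),
        "total_dist_km": float(legs.sum()),
        "mean_bearing_deg": circular_mean_deg(bearings),
    }


def trip_table(
    located_dives_with_trips: pd.DataFrame,
    nests: dict[str, tuple[float, float]],
    seasons: dict[str, str] | None = None,
    min_duration_h: float = 2.0,
    min_fixes: int = 2,
) -> pd.DataFrame:
    """Per-trip metrics table with exclusion flags (:data:`TRIP_COLUMNS`)."""
    rows = []
    for (bird_id, trip_id), sub in located_dives_with_trips.groupby(
        ["bird_id", "trip_id"], sort=True
    ):
        sub = sub.sort_values("start")
        season = seasons.get(bird_id, "") if seasons else ""
        n_loc = int(sub[["lon", "lat"]].notna().all(axis=1).sum())
        duration_h = float(
            (sub["end"].iloc[-1] - sub["start"].iloc[0]) / np.timedelta64(1, "h")
        )
        excluded, reason = False, ""
        if n_loc < min_fixes:
            excluded, reason = True, "too_few_fixes"
        elif duration_h < min_duration_h:
            excluded, reason = True, "short_trip"
        base = {
            "bird_id": bird_id, "season": season, "trip_id": trip_id,
            "start": sub["start"].iloc[0], "end": sub["end"].iloc[-1],
            "duration_h": duration_h, "n_located": n_loc,
            "max_dist_km": np.nan, "total_dist_km": np.nan, "mean_bearing_deg": np.nan,
            "excluded": excluded, "reason": reason,
        }
        if not excluded:
            base.update(trip_metrics(sub, nests[bird_id]))
            base["excluded"], base["reason"] = False, ""
        rows.append(base)
    return pd.DataFrame(rows, columns=TRIP_COLUMNS)


def hourly_centroids(
    located_dives: pd.DataFrame,
    projection: LocalProjection,
    utc_offset_h: int = LOCAL_UTC_OFFSET_H,
) -> pd.DataFrame:
    """Geographic mean of dive-linked positions per bird × local date × hour.

    Means are taken in the local planar projection and back-transformed, so
    each centroid lies in the convex hull of its member fixes.  Binning is by
    calendar date plus hour of local clock time (not hour-of-day pooled
    across days), which preserves one centroid per distinct foraging hour.
    """
    sub = located_dives.dropna(subset=["lon", "lat"]).copy()
    if len(sub) == 0:
        return pd.DataFrame(columns=["bird_id", "date", "hour", "lon", "lat", "x", "y", "n"])
    local = sub["start"] + pd.Timedelta(hours=utc_offset_h)
    sub["date"] = local.dt.date
    sub["hour"] = local.dt.hour
    x, y = projection.forward(sub["lon"].to_numpy(), sub["lat"].to_numpy())
    sub["x"], sub["y"] = x, y
    agg = (
        sub.groupby(["bird_id", "date", "hour"], sort=True)
        .agg(x=("x", "mean"), y=("y", "mean"), n=("x", "size"))
        .reset_index()
    )
    lon, lat = projection.inverse(agg["x"].to_numpy(), agg["y"].to_numpy())
    agg["lon"], agg["lat"] = lon, lat
    return agg[["bird_id", "date", "hour", "lon", "lat", "x", "y", "n"]]
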