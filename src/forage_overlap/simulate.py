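"""Ground-truthed synthetic colony: penguin deployments, sensors and fishery sets.

The generator emulates the statistical structure the downstream analysis
assumes, with full knowledge of the truth so every stage can be tested
against an oracle:

* a stylised coast: a small island ~6.5 km off a straight mainland shore,
  with the 1-nautical-mile exclusion band and a 62 km analysis buffer;
* multi-day logger deployments (1–8 days) in two seasons with unequal bird
  counts, nests assigned to the island's mainland-facing (east) or
  ocean-facing (west) side;
* foraging trips as correlated random walks attracted to a per-trip target:
  east-nesting birds head for the mainland coastal strip, west-nesting birds
  head offshore with a configurable probability of diverting to the coast;
* dive schedules whose depth mixture puts a configurable fraction (default
  0.725) of dives in the upper 30 m;
* 1 Hz depth traces with clipped surface noise, and GPS fixes generated only
  during surface intervals with dropout probability exp(-interval/tau), so
  that roughly 40% of dives acquire a linked fix;
* seasonal purse-seine sets from a Thomas cluster process, inshore in
  autumn, dispersed and southward in spring, never on land, never inside the
  exclusion band.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Point, Polygon

from .geodesy import LocalProjection
from .io import FIX_COLUMNS, SET_COLUMNS, CoastGeometry, SensorSeries

NM_M = 1852.0  # one nautical mile in metres

__all__ = [
    "SimConfig", "TripTruth", "BirdTruth", "SyntheticTruth",
    "make_coast", "simulate_trip", "render_sensors", "simulate_fishing_sets",
    "simulate_colony",
]


@dataclass
class SimConfig:
    """All knobs of the synthetic study system (defaults = study conditions)."""

    # colony design
    n_birds_autumn: int = 8
    n_birds_spring: int = 13
    p_east_nest_autumn: float = 3.0 / 8.0
    p_east_nest_spring: float = 5.0 / 13.0
    deployment_days_min: int = 1
    deployment_days_max: int = 8

    # trip process
    p_trip_per_day: float = 0.55
    trip_duration_median_h: float = 16.0
    trip_duration_sigma: float = 0.45
    trip_duration_min_h: float = 2.5
    trip_duration_max_h: float = 48.0
    p_west_coastal: float = 0.30      # west-nesting bird diverts to the coastal strip
    speed_ms: float = 1.8
    step_s: float = 30.0
    crw_persistence: float = 0.7
    target_attraction: float = 0.5

    # dive process
    dive_duration_base_s: float = 16.0
    dive_duration_per_m: float = 1.3
    dive_duration_sd_s: float = 8.0
    dive_duration_min_s: float = 6.0
    dive_duration_max_s: float = 180.0
    surface_median_s: float = 55.0
    surface_sigma: float = 0.9
    surface_min_s: float = 3.0
    frac_shallow: float = 0.725       # fraction of dives with max depth <= 30 m
    shallow_split_m: float = 30.0
    depth_min_m: float = 0.5
    depth_max_m: float = 110.0
    deep_scale_m: float = 15.0
    dive_rate_scale: float = 1.0      # 0 disables diving entirely

    # sensors
    depth_noise_sd_m: float = 0.02
    gps_day_interval_s: float = 60.0
    gps_night_interval_s: float = 900.0
    gps_dropout_tau_s: float = 120.0
    gps_error_sd_m: float = 15.0
    day_start_local_h: int = 7
    day_end_local_h: int = 19
    utc_offset_h: int = -4

    # fishery cluster process
    n_sets_autumn: int = 54
    n_sets_spring: int = 43
    parent_intensity_autumn: float = 6.0
    parent_intensity_spring: float = 5.0
    mean_offspring: float = 15.0
    cluster_sd_autumn_km: float = 1.5
    cluster_sd_spring_km: float = 4.0

    # geometry (metres in the local projection; origin = island centre)
    island_lon: float = -71.5325
    island_lat: float = -29.2567
    island_semi_ns_m: float = 1400.0
    island_semi_ew_m: float = 700.0
    channel_width_m: float = 6500.0
    mainland_extent_m: float = 120_000.0
    buffer_km: float = 62.0
    exclusion_nm: float = 1.0

    rng_seed: int = 0

    def validate(self) -> None:
        for name in (
            "p_east_nest_autumn", "p_east_nest_spring", "p_trip_per_day",
            "p_west_coastal", "frac_shallow",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in (
            "trip_duration_median_h", "speed_ms", "step_s", "surface_median_s",
            "gps_day_interval_s", "gps_night_interval_s", "gps_dropout_tau_s",
            "island_semi_ns_m", "island_semi_ew_m", "channel_width_m", "buffer_km",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.gps_day_interval_s >= self.gps_night_interval_s:
            raise ValueError("gps_day_interval must be shorter than gps_night_interval")
        if self.deployment_days_min < 1 or self.deployment_days_max < self.deployment_days_min:
            raise ValueError("invalid deployment-day range")

    def projection(self) -> LocalProjection:
        return LocalProjection(self.island_lon, self.island_lat)


@dataclass
class TripTruth:
    bird_id: str
    season: str
    start: np.datetime64
    end: np.datetime64
    path_t: np.ndarray          # datetime64[ns]
    path_xy: np.ndarray         # (n, 2) metres, local projection
    dives: pd.DataFrame         # start, end, duration_s, max_depth_m

    def position_at(self, t: np.ndarray) -> np.ndarray:
        """True (x, y) at arbitrary times by linear interpolation along the path."""
        tt = (np.asarray(t, dtype="datetime64[ns]") - self.path_t[0]) / np.timedelta64(1, "s")
        tp = (self.path_t - self.path_t[0]) / np.timedelta64(1, "s")
        x = np.interp(tt, tp, self.path_xy[:, 0])
        y = np.interp(tt, tp, self.path_xy[:, 1])
        return np.column_stack([x, y])


@dataclass
class BirdTruth:
    bird_id: str
    season: str
    nest_side: str              # "east" | "west"
    nest_xy: tuple[float, float]
    deployment_start: np.datetime64
    deployment_end: np.datetime64
    trips: list[TripTruth] = field(default_factory=list)


@dataclass
class SyntheticTruth:
    """Everything the generator knows: the oracle for downstream tests."""

    config: SimConfig
    coast: CoastGeometry
    birds: list[BirdTruth]
    fishing_sets: pd.DataFrame
    cluster_parents: dict[str, np.ndarray]

    def all_true_dives(self) -> pd.DataFrame:
        frames = []
        for bird in self.birds:
            for trip in bird.trips:
                d = trip.dives.copy()
                d["bird_id"] = bird.bird_id
                d["season"] = bird.season
                frames.append(d)
        if not frames:
            return pd.DataFrame(columns=["start", "end", "duration_s", "max_depth_m",
                                         "bird_id", "season"])
        return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Coast


def make_coast(config: SimConfig) -> CoastGeometry:
    """Stylised island + mainland separated by a channel, with regulatory zones.

    Built in the local projection and stored in lon/lat.  The island is an
    ellipse with a long north–south axis; the mainland is a half-plane slab
    whose coastline runs north–south at ``channel_width_m`` east of the
    island's eastern shore.
    """
    config.validate()
    proj = config.projection()
    theta = np.linspace(0.0, 2.0 * np.pi, 181)
    ex = config.island_semi_ew_m * np.cos(theta)
    ey = config.island_semi_ns_m * np.sin(theta)
    island = Polygon(np.column_stack([ex, ey]))

    coast_x = config.island_semi_ew_m + config.channel_width_m
    L = config.mainland_extent_m
    mainland = Polygon(
        [(coast_x, -L), (coast_x + 60_000.0, -L), (coast_x + 60_000.0, L), (coast_x, L)]
    )
    band_w = config.exclusion_nm * NM_M
    exclusion = Polygon(
        [(coast_x - band_w, -L), (coast_x, -L), (coast_x, L), (coast_x - band_w, L)]
    )
    buffer_poly = Point(0.0, 0.0).buffer(config.buffer_km * 1000.0, quad_segs=90)

    for name, g in [("island", island), ("mainland", mainland)]:
        if not g.is_valid:
            raise ValueError(f"degenerate {name} polygon")
    coast = CoastGeometry(
        island=proj.unproject_geom(island),
        mainland=proj.unproject_geom(mainland),
        exclusion_1nm=proj.unproject_geom(exclusion),
        buffer_62km=proj.unproject_geom(buffer_poly),
    )
    coast.extras["projection"] = proj
    coast.extras["projected"] = {
        "island": island, "mainland": mainland,
        "exclusion_1nm": exclusion, "buffer_62km": buffer_poly,
    }
    return coast


def _land_projected(coast: CoastGeometry, config: SimConfig):
    pj = coast.extras.get("projected")
    if pj is None:
        proj = config.projection()
        pj = {k: proj.project_geom(getattr(coast, k))
              for k in ("island", "mainland", "exclusion_1nm", "buffer_62km")}
        coast.extras["projected"] = pj
    return pj


# ---------------------------------------------------------------------------
# Trips


def _local_hour(t: np.ndarray, config: SimConfig) -> np.ndarray:
    ns = np.asarray(t, dtype="datetime64[ns]").astype("int64")
    sec_of_day = (ns // 1_000_000_000 + config.utc_offset_h * 3600) % 86400
    return sec_of_day / 3600.0


def _is_daylight(t, config: SimConfig):
    h = _local_hour(t, config)
    return (h >= config.day_start_local_h) & (h < config.day_end_local_h)


def _draw_depths(n: int, config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Mixture: P(depth <= shallow_split) = frac_shallow exactly, by construction."""
    shallow = rng.random(n) < config.frac_shallow
    depths = np.empty(n)
    lo, split = config.depth_min_m, config.shallow_split_m
    depths[shallow] = lo + (split - lo) * rng.beta(1.3, 2.0, size=int(shallow.sum()))
    n_deep = int((~shallow).sum())
    # truncated exponential on (split, depth_max]
    u = rng.random(n_deep)
    span = config.depth_max_m - split
    cdf_max = 1.0 - np.exp(-span / config.deep_scale_m)
    depths[~shallow] = split + 1e-6 - config.deep_scale_m * np.log1p(-u * cdf_max)
    return np.clip(depths, lo, config.depth_max_m)


def _dive_schedule(trip_start, trip_end, path_t, config, rng):
    """Alternate dive/surface cycles through the daylight portion of the trip."""
    rows = []
    if config.dive_rate_scale <= 0.0:
        return pd.DataFrame(columns=["start", "end", "duration_s", "max_depth_m"])
    # schedule on whole seconds so the truth sits exactly on the 1 Hz grid
    t = pd.Timestamp(trip_start).ceil("s") + pd.Timedelta(seconds=int(rng.uniform(30, 120)))
    end = pd.Timestamp(trip_end)
    while t < end:
        if not _is_daylight(np.datetime64(t), config):
            # rest/drift at the surface until next daylight window
            t = t.ceil("h") + pd.Timedelta(minutes=int(rng.uniform(0, 10)))
            continue
        depth = float(_draw_depths(1, config, rng)[0])
        dur = float(
            np.clip(
                config.dive_duration_base_s
                + config.dive_duration_per_m * depth
                + rng.normal(0.0, config.dive_duration_sd_s),
                config.dive_duration_min_s,
                config.dive_duration_max_s,
            )
        )
        dur = float(np.round(dur))
        if t + pd.Timedelta(seconds=dur) >= end:
            break
        rows.append((np.datetime64(t), np.datetime64(t + pd.Timedelta(seconds=dur)), dur, depth))
        surf = float(
            np.clip(
                rng.lognormal(np.log(config.surface_median_s), config.surface_sigma),
                config.surface_min_s,
                None,
            )
        ) / config.dive_rate_scale
        t = t + pd.Timedelta(seconds=dur + max(3.0, round(surf)))
    return pd.DataFrame(rows, columns=["start", "end", "duration_s", "max_depth_m"])


def _choose_target(side: str, config: SimConfig, rng: np.random.Generator):
    """Per-trip foraging target (projected metres) and optional waypoint."""
    coast_x = config.island_semi_ew_m + config.channel_width_m
    coastal = side == "east" or rng.random() < config.p_west_coastal
    if coastal:
        tx = coast_x - rng.uniform(1200.0, 4500.0)
        ty = rng.uniform(-12_000.0, 12_000.0)
        waypoint = None
        if side == "west":
            # round the island's southern tip before cutting inshore
            waypoint = np.array([0.0, -(config.island_semi_ns_m + 2500.0)])
        return np.array([tx, ty]), waypoint, "coastal"
    ang = np.deg2rad(rng.uniform(190.0, 280.0))  # compass SW–W sector
    dist = rng.uniform(8_000.0, 22_000.0)
    return np.array([dist * np.sin(ang), dist * np.cos(ang)]), None, "offshore"


def simulate_trip(
    nest_xy: tuple[float, float],
    side: str,
    start: np.datetime64,
    duration_h: float,
    config: SimConfig,
    coast: CoastGeometry,
    rng: np.random.Generator,
    bird_id: str = "bird",
    season: str = "autumn",
) -> TripTruth:
    """Correlated random walk departing from and returning to the nest.

    The walk is attracted first to a per-trip target (coastal strip for
    east-side birds, offshore for west-side unless diverted), then back to
    the nest; steps onto land are rejected by resampling the heading.  Dives
    are placed along the path afterwards.
    """
    config.validate()
    land = _land_projected(coast, config)
    island, mainland = land["island"], land["mainland"]
    nest = np.asarray(nest_xy, dtype=float)
    target, waypoint, _mode = _choose_target(side, config, rng)

    dt = config.step_s
    n_steps = max(2, int(round(duration_h * 3600.0 / dt)))
    step_len = config.speed_ms * dt
    xy = np.empty((n_steps + 1, 2))
    xy[0] = nest
    # initial heading: straight off the nest shore
    heading = np.arctan2(nest[0], nest[1]) if side == "west" else np.arctan2(target[0] - nest[0], target[1] - nest[1])
    goals = [waypoint, target] if waypoint is not None else [target]
    goal_idx = 0
    return_after = n_steps  # step index at which the walk turns home
    pos = nest.copy()
    for i in range(n_steps):
        # switch to homing so the return leg fits in the remaining time
        dist_home = np.hypot(*(pos - nest))
        steps_home = dist_home / step_len
        if i + steps_home * 1.3 >= n_steps and return_after > i:
            return_after = i
        if i >= return_after:
            goal = nest
            attraction = 0.9
        else:
            goal = goals[goal_idx]
            attraction = config.target_attraction
            if np.hypot(*(pos - goal)) < 1000.0:
                if goal_idx < len(goals) - 1:
                    goal_idx += 1
                else:
                    attraction = 0.15  # forage: meander near the target
        goal_bearing = np.arctan2(goal[0] - pos[0], goal[1] - pos[1])
        for _attempt in range(12):
            turn = rng.normal(0.0, 0.8 * (1.0 - config.crw_persistence))
            delta = np.angle(np.exp(1j * (goal_bearing - heading)))
            cand = heading + attraction * delta + turn
            step = step_len * np.array([np.sin(cand), np.cos(cand)])
            nxt = pos + step
            if not (
                shapely.contains_xy(island, nxt[0], nxt[1])
                or shapely.contains_xy(mainland, nxt[0], nxt[1])
            ):
                heading = cand
                pos = nxt
                break
        else:
            heading = heading + np.pi  # boxed in: turn around
        xy[i + 1] = pos
        if i >= return_after and np.hypot(*(pos - nest)) < 200.0:
            xy = xy[: i + 2]
            n_steps = i + 1
            break
    xy[-1] = nest  # trips close at the nest
    t0 = np.datetime64(start, "ns")
    path_t = t0 + (np.timedelta64(1, "s") * np.arange(xy.shape[0]) * int(dt)).astype(
        "timedelta64[s]"
    )
    trip_end = path_t[-1]
    dives = _dive_schedule(t0, trip_end, path_t, config, rng)
    return TripTruth(
        bird_id=bird_id, season=season, start=t0, end=np.datetime64(trip_end, "ns"),
        path_t=path_t.astype("datetime64[ns]"), path_xy=xy, dives=dives,
    )


# ---------------------------------------------------------------------------
# Sensor rendering


def _dive_profile(n: int, max_depth: float) -> np.ndarray:
    """Trapezoidal depth profile over n 1 Hz samples, floored well above 0.1 m."""
    u = (np.arange(n) + 0.5) / n
    shape = np.minimum(np.minimum(u / 0.3, (1.0 - u) / 0.3), 1.0)
    return np.maximum(shape * max_depth, 0.45)


def render_sensors(
    bird: BirdTruth, config: SimConfig, rng: np.random.Generator
) -> tuple[SensorSeries, pd.DataFrame]:
    """Render the 1 Hz depth trace and the duty-cycled, dropout-thinned GPS fixes.

    Depth: surface noise ~ N(0, sd) clipped at ±4 sd (so noise alone can
    never cross the 0.1 m detection threshold), each scheduled dive drawn as
    a trapezoid whose in-dive samples stay >= 0.4 m.  Fixes: within each
    daylight surface interval a Poisson(interval/tau) number of acquisitions
    (hence P(no fix) = exp(-interval/tau)), thinned to the 1-min cadence;
    at night, fixes on the 15-min grid whenever the bird is at the surface
    and away from the colony.
    """
    t0 = np.datetime64(bird.deployment_start, "ns")
    n_sec = int((bird.deployment_end - bird.deployment_start) / np.timedelta64(1, "s"))
    sd = config.depth_noise_sd_m
    depth = rng.normal(0.0, sd, size=n_sec)
    np.clip(depth, -4.0 * sd, 4.0 * sd, out=depth)

    proj = config.projection()
    fix_rows = []
    for trip in bird.trips:
        dive_starts = trip.dives["start"].to_numpy() if len(trip.dives) else np.array([], dtype="datetime64[ns]")
        dive_ends = trip.dives["end"].to_numpy() if len(trip.dives) else np.array([], dtype="datetime64[ns]")
        for ds, de, dmax in zip(
            dive_starts, dive_ends, trip.dives["max_depth_m"].to_numpy() if len(trip.dives) else [],
        ):
            i0 = int((ds - t0) / np.timedelta64(1, "s"))
            i1 = int((de - t0) / np.timedelta64(1, "s"))
            if 0 <= i0 < i1 <= n_sec:
                depth[i0:i1] = _dive_profile(i1 - i0, float(dmax)) + rng.normal(
                    0.0, sd, size=i1 - i0
                )

        # surface intervals of this trip: between consecutive dives + lead/tail
        lo = np.concatenate(([trip.start], dive_ends))
        hi = np.concatenate((dive_starts, [trip.end]))
        for s, e in zip(lo, hi):
            span = float((e - s) / np.timedelta64(1, "s"))
            if span <= 0:
                continue
            mid = s + np.timedelta64(int(span * 0.5), "s")
            if _is_daylight(mid, config):
                n_acq = rng.poisson(span / config.gps_dropout_tau_s)
                if n_acq == 0:
                    continue
                offs = np.sort(rng.uniform(0.0, span, size=n_acq))
                keep = [offs[0]]
                for o in offs[1:]:
                    if o - keep[-1] >= config.gps_day_interval_s:
                        keep.append(o)
                # whole seconds: fixes sit on the 1 Hz logger grid
                times = s + np.floor(np.asarray(keep)).astype("timedelta64[s]")
                source = "day"
            else:
                # night drift: fixes on the coarse cadence grid (integer-second maths)
                grid = int(round(config.gps_night_interval_s))
                start_s = int((s - np.datetime64(0, "s")) / np.timedelta64(1, "s"))
                first = -(-start_s // grid) * grid
                times = np.datetime64(0, "s") + np.arange(
                    first, start_s + int(span) + 1, grid, dtype=np.int64
                ).astype("timedelta64[s]")
                times = times[times <= e]
                source = "night"
            if len(times) == 0:
                continue
            pos = trip.position_at(times)
            for t, (x, y) in zip(times, pos):
                for _ in range(20):
                    gx = x + rng.normal(0.0, config.gps_error_sd_m)
                    gy = y + rng.normal(0.0, config.gps_error_sd_m)
                    land = _land_projected(
                        _coast_cache(config), config
                    )
                    if not (
                        shapely.contains_xy(land["island"], gx, gy)
                        or shapely.contains_xy(land["mainland"], gx, gy)
                    ):
                        break
                lon, lat = proj.inverse(gx, gy)
                fix_rows.append((bird.bird_id, np.datetime64(t, "ns"), float(lon), float(lat), source))

    series = SensorSeries(bird_id=bird.bird_id, start=t0, depth_m=depth, rate_hz=1.0)
    fixes = pd.DataFrame(fix_rows, columns=FIX_COLUMNS).sort_values("timestamp").reset_index(drop=True)
    return series, fixes


_COAST_CACHE: dict[tuple, CoastGeometry] = {}


def _coast_cache(config: SimConfig) -> CoastGeometry:
    key = (
        config.island_lon, config.island_lat, config.island_semi_ns_m,
        config.island_semi_ew_m, config.channel_width_m, config.buffer_km,
        config.exclusion_nm,
    )
    if key not in _COAST_CACHE:
        _COAST_CACHE[key] = make_coast(config)
    return _COAST_CACHE[key]


# ---------------------------------------------------------------------------
# Fishery


_SEASON_WINDOWS = {
    "autumn": (np.datetime64("2022-04-01"), np.datetime64("2022-07-31")),
    "spring": (np.datetime64("2022-11-01"), np.datetime64("2023-02-28")),
}


def _parent_region(season: str, config: SimConfig) -> tuple[tuple, tuple]:
    """Axis-aligned box (metres) in which cluster parents are placed."""
    coast_x = config.island_semi_ew_m + config.channel_width_m
    band = config.exclusion_nm * NM_M
    if season == "autumn":
        return (coast_x - 6000.0, coast_x - band), (-14_000.0, 14_000.0)
    return (coast_x - 30_000.0, coast_x - band), (-55_000.0, -20_000.0)


def simulate_fishing_sets(
    season: str,
    config: SimConfig,
    rng: np.random.Generator,
    coast: CoastGeometry,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Thomas cluster process of purse-seine sets, constrained to legal water.

    Poisson parents in a seasonal box, Poisson(mean_offspring) offspring per
    parent with isotropic Gaussian scatter; offspring outside the analysis
    buffer, on land, or inside the 1-nm band are rejected.  The pattern is
    then resampled to the configured per-season count.  Returns
    ``(sets, parents_xy)``.
    """
    config.validate()
    land = _land_projected(coast, config)
    n_target = config.n_sets_autumn if season == "autumn" else config.n_sets_spring
    kappa = (
        config.parent_intensity_autumn if season == "autumn" else config.parent_intensity_spring
    )
    sd = (
        config.cluster_sd_autumn_km if season == "autumn" else config.cluster_sd_spring_km
    ) * 1000.0
    (x0, x1), (y0, y1) = _parent_region(season, config)

    pts: list[np.ndarray] = []
    parents_all: list[np.ndarray] = []
    for _round in range(60):
        n_parents = rng.poisson(kappa)
        if n_parents == 0:
            continue
        parents = np.column_stack(
            [rng.uniform(x0, x1, n_parents), rng.uniform(y0, y1, n_parents)]
        )
        parents_all.append(parents)
        counts = rng.poisson(config.mean_offspring, size=n_parents)
        if counts.sum() == 0:
            if config.mean_offspring == 0.0:
                break
            continue
        offs = np.repeat(parents, counts, axis=0) + rng.normal(
            0.0, sd, size=(int(counts.sum()), 2)
        )
        ok = (
            shapely.contains_xy(land["buffer_62km"], offs[:, 0], offs[:, 1])
            & ~shapely.contains_xy(land["island"], offs[:, 0], offs[:, 1])
            & ~shapely.contains_xy(land["mainland"], offs[:, 0], offs[:, 1])
            & ~shapely.contains_xy(land["exclusion_1nm"], offs[:, 0], offs[:, 1])
        )
        pts.append(offs[ok])
        if config.mean_offspring == 0.0 or sum(len(p) for p in pts) >= n_target:
            break
    all_pts = np.concatenate(pts) if pts else np.empty((0, 2))
    parents_xy = np.concatenate(parents_all) if parents_all else np.empty((0, 2))
    if config.mean_offspring == 0.0 or all_pts.shape[0] == 0:
        return pd.DataFrame(columns=SET_COLUMNS), parents_xy
    take = rng.choice(all_pts.shape[0], size=min(n_target, all_pts.shape[0]), replace=False)
    sel = all_pts[take]

    proj = config.projection()
    lon, lat = proj.inverse(sel[:, 0], sel[:, 1])
    w0, w1 = _SEASON_WINDOWS[season]
    days = int((w1 - w0) / np.timedelta64(1, "D"))
    dates = w0 + rng.integers(0, days + 1, size=len(sel)).astype("timedelta64[D]")
    if season == "autumn":
        species = np.full(len(sel), "anchoveta")
    else:
        species = rng.choice(
            ["jack_mackerel", "chub_mackerel", "anchoveta"],
            p=np.array([26.0, 10.0, 5.0]) / 41.0,
            size=len(sel),
        )
    sets = pd.DataFrame(
        {
            "set_id": [f"{season[0]}{i:04d}" for i in range(len(sel))],
            "date": pd.to_datetime(dates),
            "lon": lon,
            "lat": lat,
            "species": species,
            "season": season,
        }
    )
    return sets.sort_values("date").reset_index(drop=True), parents_xy


# ---------------------------------------------------------------------------
# Whole colony


_DEPLOY_WINDOWS = {
    "autumn": (np.datetime64("2022-06-15"), np.datetime64("2022-06-22")),
    "spring": (np.datetime64("2022-11-26"), np.datetime64("2022-12-14")),
}


def _nest_position(side: str, config: SimConfig, rng: np.random.Generator):
    ang = rng.uniform(-55.0, 55.0)  # degrees around the facing axis
    ang = np.deg2rad(ang)
    sx = 1.0 if side == "east" else -1.0
    x = sx * config.island_semi_ew_m * np.cos(ang) * 1.001
    y = config.island_semi_ns_m * np.sin(ang) * 1.001
    return (float(x), float(y))


def simulate_colony(
    config: SimConfig | None = None, seed: int | None = None
) -> tuple[SyntheticTruth, dict[str, SensorSeries], pd.DataFrame]:
    """Simulate the full two-season colony and render all sensor output.

    Returns ``(truth, series_by_bird, fixes)``; fishery sets live on
    ``truth.fishing_sets``.  With a fixed seed the output is reproducible
    bit-for-bit.
    """
    config = config or SimConfig()
    config.validate()
    rng = np.random.default_rng(config.rng_seed if seed is None else seed)
    coast = make_coast(config)

    birds: list[BirdTruth] = []
    k = 0
    for season, n_birds, p_east in [
        ("autumn", config.n_birds_autumn, config.p_east_nest_autumn),
        ("spring", config.n_birds_spring, config.p_east_nest_spring),
    ]:
        w0, w1 = _DEPLOY_WINDOWS[season]
        for _ in range(n_birds):
            k += 1
            bird_id = f"{season[0]}{k:02d}"
            side = "east" if rng.random() < p_east else "west"
            nest = _nest_position(side, config, rng)
            days = int(rng.integers(config.deployment_days_min, config.deployment_days_max + 1))
            start_day = w0 + rng.integers(0, max(1, int((w1 - w0) / np.timedelta64(1, "D")))).astype(
                "timedelta64[D]"
            )
            dep_start = np.datetime64(start_day, "ns") + np.timedelta64(10, "h")  # 06:00 local
            dep_end = dep_start + np.timedelta64(days * 24, "h")
            bird = BirdTruth(
                bird_id=bird_id, season=season, nest_side=side, nest_xy=nest,
                deployment_start=dep_start, deployment_end=dep_end,
            )
            t_free = dep_start  # trips never overlap: next departure waits out the last
            for d in range(days):
                if rng.random() >= config.p_trip_per_day:
                    continue
                dur = float(
                    np.clip(
                        rng.lognormal(np.log(config.trip_duration_median_h), config.trip_duration_sigma),
                        config.trip_duration_min_h,
                        config.trip_duration_max_h,
                    )
                )
                t_start = (
                    dep_start
                    + np.timedelta64(d * 24, "h")
                    + np.timedelta64(int(rng.uniform(60, 150)), "m")
                )
                if t_start < t_free:
                    continue
                max_h = float((dep_end - t_start) / np.timedelta64(1, "h")) - 0.5
                if max_h < config.trip_duration_min_h:
                    continue
                dur = min(dur, max_h)
                trip = simulate_trip(
                    nest, side, t_start, dur, config, coast, rng,
                    bird_id=bird_id, season=season,
                )
                bird.trips.append(trip)
                t_free = trip.end + np.timedelta64(1, "h")
            birds.append(bird)

    series_by_bird: dict[str, SensorSeries] = {}
    fix_frames = []
    for bird in birds:
        series, fixes = render_sensors(bird, config, rng)
        series_by_bird[bird.bird_id] = series
        fix_frames.append(fixes)
    fix_frames = [f for f in fix_frames if len(f)]
    fixes = (
        pd.concat(fix_frames, ignore_index=True) if fix_frames else pd.DataFrame(columns=FIX_COLUMNS)
    )

    set_frames = []
    parents = {}
    for season in ("autumn", "spring"):
        sets, par = simulate_fishing_sets(season, config, rng, coast)
        set_frames.append(sets)
        parents[season] = par
    fishing_sets = pd.concat(set_frames, ignore_index=True)

    truth = SyntheticTruth(
        config=config, coast=coast, birds=birds,
        fishing_sets=fishing_sets, cluster_parents=parents,
    )
    return truth, series_by_bird, fixes
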