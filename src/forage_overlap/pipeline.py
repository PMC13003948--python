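"""End-to-end analysis: synthetic colony -> dives -> trips -> UDs -> overlap -> PCF.

The stages mirror how the analysis runs on real logger downloads: detect
dives per bird, link them to surface-interval fixes, drop near-shore
positions, segment trips and compute their metrics, aggregate located dives
to hourly centroids, fit the pooled forager UD and per-season fishery UDs,
erase land/regulatory zones, intersect isopleths, and estimate the
cross-type pair correlation between foraging locations and fishing sets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.ops import unary_union

from . import io as fio
from .dives import DiveDetector, build_surface_intervals, link_dives, share_below
from .geodesy import LocalProjection
from .homerange import (
    BandwidthError, IsoplethPolygon, KernelHomeRange, erase_excluded,
    normal_scale_bandwidth,
)
from .overlap import CrossPairCorrelation, OverlapResult, kde_overlap
from .season import SeasonEffect, fit_season_model
from .simulate import SimConfig, SyntheticTruth, simulate_colony
from .trips import filter_nearshore, hourly_centroids, segment_trips, trip_table

SEASON_RESPONSES = ["duration_h", "total_dist_km", "home_range_km2",
                    "mean_depth_m", "max_depth_m"]


@dataclass
class PipelineResult:
    config: SimConfig
    truth: SyntheticTruth
    projection: LocalProjection
    dives: pd.DataFrame                  # all detected dives, linked where possible
    located: pd.DataFrame                # located + near-shore-filtered, with trip ids
    trips: pd.DataFrame
    centroids: pd.DataFrame
    penguin_isopleths: list[IsoplethPolygon]
    fishery_isopleths: dict[str, list[IsoplethPolygon]]
    overlaps: list[OverlapResult]
    pcf: dict[str, dict]
    season_effects: list[SeasonEffect] = field(default_factory=list)
    counts: dict = field(default_factory=dict)

    def overlap_table(self) -> pd.DataFrame:
        return pd.DataFrame([vars(o) for o in self.overlaps])


def _per_trip_responses(located: pd.DataFrame, projection: LocalProjection) -> pd.DataFrame:
    """Per-trip depth stats and a per-trip 95%-isopleth home range (km²)."""
    rows = []
    for trip_id, sub in located.groupby("trip_id", sort=False):
        x, y = projection.forward(sub["lon"].to_numpy(), sub["lat"].to_numpy())
        pts = np.column_stack([x, y])
        hr = np.nan
        if len(pts) >= 3:
            try:
                hr_model = KernelHomeRange(cell_m=200.0, levels=(0.95,))
                try:
                    hr_model.fit(pts)
                except BandwidthError:
                    hr_model = KernelHomeRange(
                        cell_m=200.0, levels=(0.95,),
                        bandwidth=normal_scale_bandwidth(pts) + np.eye(2) * 100.0**2,
                    )
                    hr_model.fit(pts)
                hr = hr_model.contours_[0].area_m2 / 1e6
            except (ValueError, np.linalg.LinAlgError):
                hr = np.nan
        rows.append(
            {
                "trip_id": trip_id,
                "home_range_km2": hr,
                "mean_depth_m": float(sub["max_depth_m"].mean()),
                "max_depth_m": float(sub["max_depth_m"].max()),
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(
    config: SimConfig | None = None,
    seed: int | None = None,
    kde_cell_m: float = 250.0,
    levels: tuple = (0.5, 0.75, 0.95),
    nearshore_radius_m: float = 100.0,
    pcf_r: np.ndarray | None = None,
    fit_season_models: bool = True,
) -> PipelineResult:
    """Run the full pipeline on a synthetic colony and return every product."""
    config = config or SimConfig()
    if seed is not None:
        config = SimConfig(**{**vars(config), "rng_seed": seed})
    truth, series_by_bird, fixes = simulate_colony(config)
    projection = config.projection()
    coast = truth.coast

    # dives per bird, linked to preceding-surface-interval fixes
    detector = DiveDetector()
    linked_frames = []
    for bird_id, series in series_by_bird.items():
        det = detector.transform(series)
        if len(det) == 0:
            continue
        sub_fix = fixes[fixes["bird_id"] == bird_id]
        intervals, fx = build_surface_intervals(
            det, (series.start, series.times()[-1]), sub_fix
        )
        linked_frames.append(link_dives(det, intervals, fx))
    dives = (
        pd.concat(linked_frames, ignore_index=True)
        if linked_frames
        else pd.DataFrame(columns=fio.DIVE_COLUMNS)
    )

    located = dives.dropna(subset=["lon", "lat"]).reset_index(drop=True)
    located = filter_nearshore(located, coast.island, projection, nearshore_radius_m)
    located = segment_trips(located)

    seasons = {b.bird_id: b.season for b in truth.birds}
    nests = {
        b.bird_id: tuple(np.atleast_1d(v)[0] for v in projection.inverse(*b.nest_xy))
        for b in truth.birds
    }
    trips = trip_table(located, nests, seasons)
    extra = _per_trip_responses(located, projection)
    trips = trips.merge(extra, on="trip_id", how="left")

    centroids = hourly_centroids(located, projection, config.utc_offset_h)

    # pooled forager UD; per-season fishery UDs
    pen_model = KernelHomeRange(cell_m=kde_cell_m, levels=levels)
    pen_model.fit(centroids[["x", "y"]].to_numpy())
    penguin_iso = erase_excluded(
        pen_model.isopleths(projection), coast, zones=("mainland", "island")
    )

    fishery_iso: dict[str, list[IsoplethPolygon]] = {}
    sets = truth.fishing_sets
    for season in ("autumn", "spring"):
        pts = sets[sets["season"] == season]
        x, y = projection.forward(pts["lon"].to_numpy(), pts["lat"].to_numpy())
        model = KernelHomeRange(cell_m=kde_cell_m, levels=levels)
        model.fit(np.column_stack([x, y]))
        fishery_iso[season] = erase_excluded(
            model.isopleths(projection), coast,
            zones=("mainland", "island", "exclusion_1nm"),
        )

    # coastal core: the inshore part of the forager isopleth (within 10 km of
    # the mainland), reported alongside the whole-range overlap
    land_pj = coast.extras.get("projected")
    coastal_strip = projection.unproject_geom(
        projection.project_geom(coast.mainland).buffer(10_000.0)
    )
    overlaps: list[OverlapResult] = []
    for season in ("autumn", "spring"):
        by_level = {iso.level: iso for iso in fishery_iso[season]}
        for p_iso in penguin_iso:
            f_iso = by_level[p_iso.level]
            overlaps.append(kde_overlap(p_iso, f_iso, season=season))
            if p_iso.level == min(levels):
                overlaps.append(
                    kde_overlap(
                        p_iso, f_iso, season=season,
                        subregion=coastal_strip, subregion_label="coastal_core",
                    )
                )

    # cross-PCF in the water part of the analysis buffer
    if land_pj is None:
        land_pj = {
            k: projection.project_geom(getattr(coast, k))
            for k in ("island", "mainland", "buffer_62km")
        }
    window = land_pj["buffer_62km"].difference(
        unary_union([land_pj["island"], land_pj["mainland"]])
    )
    pcf: dict[str, dict] = {}
    cent_xy = centroids[["x", "y"]].to_numpy()
    for season in ("autumn", "spring"):
        pts = sets[sets["season"] == season]
        if len(pts) < 2 or len(cent_xy) < 2:
            continue
        sx, sy = projection.forward(pts["lon"].to_numpy(), pts["lat"].to_numpy())
        est = CrossPairCorrelation(window=window, r=pcf_r).fit(
            cent_xy, np.column_stack([sx, sy])
        )
        pcf[season] = {"curve": est.curve_, "summary": est.summary_}

    season_effects: list[SeasonEffect] = []
    if fit_season_models:
        usable = trips[~trips["excluded"]]
        for resp in SEASON_RESPONSES:
            try:
                season_effects.append(fit_season_model(usable.dropna(subset=[resp]), resp))
            except (ValueError, RuntimeError):
                continue

    n_dives = len(dives)
    n_linked = int(dives[["lon", "lat"]].notna().all(axis=1).sum())
    counts = {
        "n_birds": len(truth.birds),
        "n_trips": int(trips.shape[0]),
        "n_trips_excluded": int(trips["excluded"].sum()),
        "n_dives": n_dives,
        "n_dives_linked": n_linked,
        "located_fraction": n_linked / n_dives if n_dives else np.nan,
        "pct_dives_le_30m": share_below(dives, 30.0) if n_dives else np.nan,
        "n_hourly_centroids": int(len(centroids)),
        "n_sets_autumn": int((sets["season"] == "autumn").sum()),
        "n_sets_spring": int((sets["season"] == "spring").sum()),
    }
    return PipelineResult(
        config=config, truth=truth, projection=projection, dives=dives,
        located=located, trips=trips, centroids=centroids,
        penguin_isopleths=penguin_iso, fishery_isopleths=fishery_iso,
        overlaps=overlaps, pcf=pcf, season_effects=season_effects, counts=counts,
    )


def write_outputs(result: PipelineResult, outdir: str | Path) -> None:
    """Write every pipeline product as CSV / GeoJSON / JSON under ``outdir``."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    result.dives.to_csv(out / "dives.csv", index=False)
    result.trips.to_csv(out / "trip_metrics.csv", index=False)
    result.centroids.drop(columns=["x", "y"]).to_csv(out / "hourly_centroids.csv", index=False)
    fio.write_isopleths(result.penguin_isopleths, out / "penguin_isopleths.geojson")
    for season, iso in result.fishery_isopleths.items():
        fio.write_isopleths(iso, out / f"fishery_isopleths_{season}.geojson")
    result.overlap_table().to_csv(out / "overlap.csv", index=False)
    for season, d in result.pcf.items():
        curve = d["curve"]
        pd.DataFrame(
            {"r_m": curve.r, "g_iso": curve.g_iso, "g_trans": curve.g_trans}
        ).to_csv(out / f"cross_pcf_{season}.csv", index=False)
    fio.write_coast(result.truth.coast, out / "coast.geojson")
    summary = {
        "counts": result.counts,
        "penguin_kde_km2": {
            str(i.level): i.area_km2 for i in result.penguin_isopleths
        },
        "fishery_kde_km2": {
            s: {str(i.level): i.area_km2 for i in iso}
            for s, iso in result.fishery_isopleths.items()
        },
        "pcf_summary": {
            s: {c: d["summary"][c] for c in d["summary"]} for s, d in result.pcf.items()
        },
        "season_effects": [e.summary_row() for e in result.season_effects],
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=float)
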