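"""The synthetic colony generator against its own ground truth."""

import numpy as np
import pandas as pd
import pytest
import shapely

from forage_overlap.dives import detect_dives
from forage_overlap.simulate import (
    SimConfig, make_coast, render_sensors, simulate_colony,
    simulate_fishing_sets, simulate_trip, _draw_depths,
)


class TestConfigValidation:
    def test_probability_bounds(self):
        with pytest.raises(ValueError):
            SimConfig(p_east_nest_autumn=1.5).validate()

    def test_positive_rates(self):
        with pytest.raises(ValueError):
            SimConfig(surface_median_s=0.0).validate()

    def test_cadence_ordering(self):
        with pytest.raises(ValueError):
            SimConfig(gps_day_interval_s=900.0, gps_night_interval_s=60.0).validate()


class TestCoast:
    def test_channel_width_is_6p5_km(self):
        coast = make_coast(SimConfig())
        pj = coast.extras["projected"]
        assert pj["island"].distance(pj["mainland"]) == pytest.approx(6500.0, abs=5.0)

    def test_exclusion_band_is_one_nautical_mile(self):
        coast = make_coast(SimConfig())
        pj = coast.extras["projected"]
        xmin, _, xmax, _ = pj["exclusion_1nm"].bounds
        assert xmax - xmin == pytest.approx(1852.0, abs=0.5)

    def test_buffer_radius_62_km(self):
        coast = make_coast(SimConfig())
        pj = coast.extras["projected"]
        xmin, ymin, xmax, ymax = pj["buffer_62km"].bounds
        assert (xmax - xmin) / 2 == pytest.approx(62_000.0, rel=1e-3)
        assert pj["buffer_62km"].contains(pj["island"])


class TestTrips:
    def test_zero_dive_rate_empty_schedule_path_closed(self):
        cfg = SimConfig(dive_rate_scale=0.0)
        coast = make_coast(cfg)
        rng = np.random.default_rng(0)
        trip = simulate_trip(
            (cfg.island_semi_ew_m, 0.0), "east",
            np.datetime64("2022-06-16T12:00:00"), 8.0, cfg, coast, rng,
        )
        assert len(trip.dives) == 0
        np.testing.assert_allclose(trip.path_xy[-1], trip.path_xy[0], atol=1e-9)

    def test_east_birds_dive_east_of_long_axis(self):
        """Monte-Carlo: east-nesting birds' dives concentrate east of the island."""
        cfg = SimConfig(trip_duration_median_h=6.0)
        coast = make_coast(cfg)
        rng = np.random.default_rng(5)
        east, total = 0, 0
        for k in range(120):
            trip = simulate_trip(
                (cfg.island_semi_ew_m, 0.0), "east",
                np.datetime64("2022-06-16T14:00:00"), 6.0, cfg, coast, rng,
            )
            if len(trip.dives) == 0:
                continue
            pos = trip.position_at(trip.dives["start"].to_numpy())
            east += int((pos[:, 0] > 0).sum())
            total += len(pos)
        assert total > 1000
        assert east / total > 0.95

    def test_depth_mixture_fraction(self):
        depths = _draw_depths(10_000, SimConfig(), np.random.default_rng(2))
        assert np.mean(depths <= 30.0) * 100 == pytest.approx(72.5, abs=2.0)
        assert depths.min() >= 0.5 and depths.max() <= 110.0

    def test_dives_inside_trips(self, small_colony):
        truth, _, _ = small_colony
        for bird in truth.birds:
            for trip in bird.trips:
                if len(trip.dives):
                    assert (trip.dives["start"].to_numpy() >= trip.start).all()
                    assert (trip.dives["end"].to_numpy() <= trip.end).all()

    def test_paths_stay_in_water(self, small_colony):
        truth, _, _ = small_colony
        pj = truth.coast.extras["projected"]
        for bird in truth.birds:
            for trip in bird.trips:
                xy = trip.path_xy[1:-1]  # nest itself sits on the shoreline
                on_land = shapely.contains_xy(pj["island"], xy[:, 0], xy[:, 1]) | \
                    shapely.contains_xy(pj["mainland"], xy[:, 0], xy[:, 1])
                assert not on_land.any()


class TestSensors:
    def test_rendered_dives_recovered_exactly(self, small_colony):
        """Detection at the standard thresholds recovers the truth bit-exactly."""
        truth, series_by_bird, _ = small_colony
        td = truth.all_true_dives()
        for bird in truth.birds:
            det = detect_dives(series_by_bird[bird.bird_id])
            tsub = td[td["bird_id"] == bird.bird_id].sort_values("start")
            assert len(det) == len(tsub)
            if len(det):
                assert (det["start"].to_numpy() == tsub["start"].to_numpy()).all()
                assert (det["end"].to_numpy() == tsub["end"].to_numpy()).all()
                np.testing.assert_allclose(
                    det["max_depth_m"], tsub["max_depth_m"], atol=0.1
                )

    def test_no_dropout_links_every_dive(self):
        """With an effectively zero dropout scale every surface interval gets a fix."""
        cfg = SimConfig(
            n_birds_autumn=1, n_birds_spring=0, deployment_days_min=2,
            deployment_days_max=2, gps_dropout_tau_s=0.5, rng_seed=3,
        )
        truth, series, fixes = simulate_colony(cfg)
        bird = truth.birds[0]
        day_dives = 0
        linked = 0
        from forage_overlap.simulate import _is_daylight

        for trip in bird.trips:
            dives = trip.dives
            lo = np.concatenate(([trip.start], dives["end"].to_numpy()))
            for k, ds in enumerate(dives["start"].to_numpy()):
                mid = lo[k] + (ds - lo[k]) / 2
                if not _is_daylight(mid, cfg):
                    continue
                day_dives += 1
                span = fixes[(fixes.timestamp >= lo[k]) & (fixes.timestamp <= ds)]
                linked += int(len(span) > 0)
        assert day_dives > 50
        assert linked == day_dives

    def test_night_fixes_on_cadence_grid(self, small_colony):
        truth, _, fixes = small_colony
        night = fixes[fixes["source"] == "night"].sort_values("timestamp")
        assert len(night) > 5
        secs = night["timestamp"].astype("int64") // 1_000_000_000
        assert (secs % 900 == 0).all()

    def test_no_fix_on_land(self, small_colony):
        truth, _, fixes = small_colony
        proj = truth.config.projection()
        pj = truth.coast.extras["projected"]
        x, y = proj.forward(fixes["lon"].to_numpy(), fixes["lat"].to_numpy())
        pts = np.column_stack([x, y])
        assert not shapely.contains_xy(pj["island"], pts[:, 0], pts[:, 1]).any()
        assert not shapely.contains_xy(pj["mainland"], pts[:, 0], pts[:, 1]).any()


class TestFishery:
    def test_default_counts(self, small_colony):
        truth, _, _ = small_colony
        counts = truth.fishing_sets["season"].value_counts()
        assert counts["autumn"] == 54
        assert counts["spring"] == 43

    def test_zero_offspring_empty(self):
        cfg = SimConfig(mean_offspring=0.0)
        coast = make_coast(cfg)
        sets, _ = simulate_fishing_sets("autumn", cfg, np.random.default_rng(0), coast)
        assert len(sets) == 0

    def test_sets_in_legal_water(self, small_colony):
        truth, _, _ = small_colony
        cfg = truth.config
        proj = cfg.projection()
        pj = truth.coast.extras["projected"]
        sets = truth.fishing_sets
        x, y = proj.forward(sets["lon"].to_numpy(), sets["lat"].to_numpy())
        assert shapely.contains_xy(pj["buffer_62km"], x, y).all()
        assert not shapely.contains_xy(pj["exclusion_1nm"], x, y).any()
        assert not shapely.contains_xy(pj["mainland"], x, y).any()
        assert not shapely.contains_xy(pj["island"], x, y).any()

    def test_season_dates_match_windows(self, small_colony):
        truth, _, _ = small_colony
        sets = truth.fishing_sets
        months = pd.DatetimeIndex(sets["date"]).month
        autumn = sets["season"] == "autumn"
        assert months[autumn].isin([4, 5, 6, 7]).all()
        assert months[~autumn].isin([11, 12, 1, 2]).all()


class TestDeterminism:
    def test_identical_seeds_identical_output(self, small_config):
        t1, s1, f1 = simulate_colony(small_config)
        t2, s2, f2 = simulate_colony(small_config)
        assert f1.equals(f2)
        assert t1.fishing_sets.equals(t2.fishing_sets)
        for b in s1:
            np.testing.assert_array_equal(s1[b].depth_m, s2[b].depth_m)
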