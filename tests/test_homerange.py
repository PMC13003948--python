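"""Bandwidth selection, KDE evaluation, isopleth extraction, erasing, areas."""

import numpy as np
import pytest
from shapely.geometry import MultiPolygon, Polygon, box

from forage_overlap.geodesy import LocalProjection
from forage_overlap.homerange import (
    BandwidthError, IsoplethPolygon, KernelHomeRange, erase_excluded,
    evaluate_kde, normal_scale_bandwidth, plugin_bandwidth, volume_contours,
)
from forage_overlap.io import CoastGeometry


class TestPluginBandwidth:
    def test_scale_equivariance(self, rng):
        X = rng.standard_normal((300, 2))
        H1 = plugin_bandwidth(X)
        H2 = plugin_bandwidth(X * 5.0)
        np.testing.assert_allclose(H2, 25.0 * H1, rtol=1e-5)

    def test_close_to_normal_scale_on_gaussian_sample(self):
        """n = 1,000 standard normal: diagonal within 30% of n^(-1/3), off-diag small."""
        X = np.random.default_rng(42).standard_normal((1000, 2))
        H = plugin_bandwidth(X)
        ref = 1000 ** (-1.0 / 3.0)
        assert abs(H[0, 0] - ref) / ref < 0.30
        assert abs(H[1, 1] - ref) / ref < 0.30
        assert abs(H[0, 1]) < 0.3 * ref

    def test_duplicated_sample_shrinks_bandwidth(self, rng):
        X = rng.standard_normal((200, 2))
        H1 = plugin_bandwidth(X)
        H2 = plugin_bandwidth(np.vstack([X, X]))
        assert np.linalg.det(H2) < np.linalg.det(H1)

    def test_too_few_points(self):
        with pytest.raises(BandwidthError, match="normal_scale"):
            plugin_bandwidth(np.random.default_rng(0).standard_normal((5, 2)))

    def test_collinear_points(self):
        t = np.linspace(0, 1, 50)
        X = np.column_stack([t, 2.0 * t])
        with pytest.raises(BandwidthError):
            plugin_bandwidth(X)


class TestEvaluateKde:
    def test_single_point_density_at_center(self):
        ud = evaluate_kde(np.array([[0.0, 0.0]]), np.eye(2), cell_m=0.25, margin_sigmas=6)
        ix = int(round((0.0 - ud.x0) / ud.cell_m))
        iy = int(round((0.0 - ud.y0) / ud.cell_m))
        # renormalisation over the grid nudges the value by < 0.1%
        assert ud.density[iy, ix] == pytest.approx(1.0 / (2 * np.pi), rel=1e-3)

    def test_mass_is_one(self, rng):
        X = rng.normal(0.0, 50.0, (40, 2))
        ud = evaluate_kde(X, 400.0 * np.eye(2), cell_m=5.0)
        assert ud.total_mass() == pytest.approx(1.0, abs=1e-6)

    def test_matches_naive_sum_of_gaussians(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.5], [-0.5, 1.0]])
        H = np.array([[1.0, 0.3], [0.3, 0.8]])
        ud = evaluate_kde(pts, H, cell_m=0.7, margin_sigmas=6)
        Hinv = np.linalg.inv(H)
        norm = 1.0 / (2 * np.pi * np.sqrt(np.linalg.det(H)))
        naive = np.zeros_like(ud.density)
        for p in pts:
            for iy in range(ud.ny):
                for ix in range(ud.nx):
                    d = np.array([ud.x0 + ix * ud.cell_m - p[0], ud.y0 + iy * ud.cell_m - p[1]])
                    naive[iy, ix] += norm * np.exp(-0.5 * d @ Hinv @ d)
        naive /= len(pts)
        naive /= naive.sum() * ud.cell_m**2
        np.testing.assert_allclose(ud.density, naive, atol=1e-12)

    def test_grid_too_small_errors(self):
        with pytest.raises(ValueError, match="mass"):
            evaluate_kde(
                np.array([[0.0, 0.0]]), np.eye(2), cell_m=0.5,
                bounds=(-1.0, -1.0, 1.0, 1.0),
            )


class TestVolumeContours:
    def _gauss_ud(self, n=4000, seed=0, cell=0.08):
        X = np.random.default_rng(seed).standard_normal((n, 2))
        model = KernelHomeRange(cell_m=cell, bandwidth=0.05 * np.eye(2))
        return model.fit(X)

    def test_nesting(self):
        model = self._gauss_ud()
        areas = [c.area_m2 for c in model.contours_]
        assert areas[0] <= areas[1] <= areas[2]

    def test_mass_inside_threshold_cells(self):
        model = self._gauss_ud()
        cell_mass = model.ud_.cell_m ** 2 * model.ud_.density.max()
        for c in model.contours_:
            assert c.cell_mass >= c.level
            assert c.cell_mass <= c.level + max(cell_mass, 1e-3)

    def test_gaussian_hdr_area_analytic(self):
        """50% HDR of N(0, I) has area pi * chi^2_2(0.5) = 2 pi ln 2."""
        model = self._gauss_ud()
        a50 = model.contours_[0].area_m2
        assert a50 == pytest.approx(2 * np.pi * np.log(2), rel=0.10)

    def test_level_validation(self):
        model = self._gauss_ud(n=50, cell=0.2)
        with pytest.raises(ValueError):
            volume_contours(model.ud_, (1.5,))

    def test_translation_equivariance(self, rng):
        X = rng.normal(0.0, 1.0, (150, 2))
        H = 0.2 * np.eye(2)
        m1 = KernelHomeRange(cell_m=0.1, bandwidth=H).fit(X)
        shift = np.array([1000.0, -500.0])
        m2 = KernelHomeRange(cell_m=0.1, bandwidth=H).fit(X + shift)
        for c1, c2 in zip(m1.contours_, m2.contours_):
            assert c2.area_m2 == pytest.approx(c1.area_m2, rel=1e-6)
            c1c = np.array(c1.geometry.centroid.coords[0])
            c2c = np.array(c2.geometry.centroid.coords[0])
            np.testing.assert_allclose(c2c - c1c, shift, atol=1e-6)

    def test_grid_refinement_stability(self, rng):
        """Halving the cell size changes isopleth areas by < 2%."""
        X = np.vstack([
            rng.normal(0.0, 300.0, (150, 2)),
            rng.normal([800.0, 400.0], 200.0, (100, 2)),
        ])
        H = plugin_bandwidth(X)
        coarse = KernelHomeRange(cell_m=50.0, bandwidth=H).fit(X)
        fine = KernelHomeRange(cell_m=25.0, bandwidth=H).fit(X)
        for c, f in zip(coarse.contours_, fine.contours_):
            assert f.area_m2 == pytest.approx(c.area_m2, rel=0.02)


def _coast_for_erase():
    proj = LocalProjection(-71.5325, -29.2567)
    island = proj.unproject_geom(box(-500, -500, 500, 500))
    mainland = proj.unproject_geom(box(7000, -50_000, 60_000, 50_000))
    excl = proj.unproject_geom(box(5148, -50_000, 7000, 50_000))
    buffer62 = proj.unproject_geom(
        box(-62_000, -62_000, 62_000, 62_000)
    )
    return proj, CoastGeometry(island=island, mainland=mainland,
                               exclusion_1nm=excl, buffer_62km=buffer62)


class TestEraseExcluded:
    def _iso(self, proj, poly_xy):
        geom = proj.unproject_geom(poly_xy)
        if geom.geom_type == "Polygon":
            geom = MultiPolygon([geom])
        from forage_overlap.geodesy import geodesic_area_km2

        a = geodesic_area_km2(geom)
        return IsoplethPolygon(level=0.5, geometry=geom, pre_erase_area_km2=a, area_km2=a)

    def test_fully_on_land_becomes_empty(self):
        proj, coast = _coast_for_erase()
        iso = self._iso(proj, box(10_000, 0, 12_000, 2_000))
        out = erase_excluded([iso], coast, zones=("mainland", "island"))[0]
        assert out.area_km2 == 0.0

    def test_fully_at_sea_unchanged(self):
        proj, coast = _coast_for_erase()
        iso = self._iso(proj, box(-4000, -4000, -1000, -1000))
        out = erase_excluded([iso], coast, zones=("mainland", "island"))[0]
        assert out.area_km2 == pytest.approx(iso.pre_erase_area_km2, rel=1e-9)

    def test_half_overlap_halves_area(self):
        proj, coast = _coast_for_erase()
        # rectangle straddling the mainland coastline at x = 7,000
        iso = self._iso(proj, box(5_000, 0, 9_000, 2_000))
        out = erase_excluded([iso], coast, zones=("mainland",))[0]
        assert out.area_km2 == pytest.approx(iso.pre_erase_area_km2 / 2.0, rel=0.01)
        # with the 1-nm band erased too, only [5000, 5148] x [0, 2000] remains
        out2 = erase_excluded([iso], coast, zones=("mainland", "exclusion_1nm"))[0]
        assert out2.area_km2 == pytest.approx(
            iso.pre_erase_area_km2 * 148.0 / 4000.0, rel=0.02
        )

    def test_post_erase_never_exceeds_pre_erase(self, default_pipeline):
        for iso in default_pipeline.penguin_isopleths:
            assert iso.area_km2 <= iso.pre_erase_area_km2 + 1e-9
        for isos in default_pipeline.fishery_isopleths.values():
            for iso in isos:
                assert iso.area_km2 <= iso.pre_erase_area_km2 + 1e-9
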