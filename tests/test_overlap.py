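"""Isopleth overlap metrics and the cross-type pair correlation function."""

import numpy as np
import pytest
from shapely.geometry import MultiPolygon, box

from forage_overlap.geodesy import LocalProjection, geodesic_area_km2
from forage_overlap.homerange import IsoplethPolygon
from forage_overlap.overlap import (
    CrossPairCorrelation, _epanechnikov, _isotropic_weight_poly,
    _isotropic_weight_rect, _translation_weight_poly, _translation_weight_rect,
    cross_pcf, kde_overlap, pcf_summary,
)

PROJ = LocalProjection(-71.5325, -29.2567)


def iso_of(poly_xy, level=0.5):
    geom = PROJ.unproject_geom(poly_xy)
    if geom.geom_type == "Polygon":
        geom = MultiPolygon([geom])
    a = geodesic_area_km2(geom)
    return IsoplethPolygon(level=level, geometry=geom, pre_erase_area_km2=a, area_km2=a)


class TestKdeOverlap:
    def test_identical_polygons_100pct(self):
        a = iso_of(box(0, 0, 5000, 5000))
        r = kde_overlap(a, a)
        assert r.relative_pct == pytest.approx(100.0, abs=1e-6)
        assert r.overlap_km2 == pytest.approx(a.area_km2, rel=1e-9)

    def test_disjoint_zero(self):
        a = iso_of(box(0, 0, 5000, 5000))
        b = iso_of(box(10_000, 10_000, 15_000, 15_000))
        r = kde_overlap(a, b)
        assert r.overlap_km2 == 0.0
        assert r.relative_pct == 0.0

    def test_relative_recomputes_from_absolute(self):
        a = iso_of(box(0, 0, 10_000, 10_000))
        b = iso_of(box(5_000, 0, 15_000, 10_000))
        r = kde_overlap(a, b)
        assert r.relative_pct == pytest.approx(100.0 * r.overlap_km2 / r.penguin_area_km2)
        assert r.relative_pct == pytest.approx(50.0, abs=0.1)
        assert r.overlap_km2 <= min(r.penguin_area_km2, r.fishery_area_km2)

    def test_subregion_restriction(self):
        a = iso_of(box(0, 0, 10_000, 10_000))
        b = iso_of(box(5_000, 0, 15_000, 10_000))
        east_half = PROJ.unproject_geom(box(5_000, -20_000, 30_000, 20_000))
        r = kde_overlap(a, b, subregion=east_half, subregion_label="coastal")
        assert r.relative_pct == pytest.approx(100.0, abs=0.1)
        assert r.subregion == "coastal"

    def test_level_mismatch(self):
        with pytest.raises(ValueError):
            kde_overlap(iso_of(box(0, 0, 1, 1), 0.5), iso_of(box(0, 0, 1, 1), 0.75))


class TestEdgeCorrectionWeights:
    """Rectangle closed forms against independent polygon-geometry computation."""

    def test_isotropic_rect_vs_polygon(self, rng):
        rect = (0.0, 0.0, 1000.0, 800.0)
        x = rng.uniform(0, 1000, 60)
        y = rng.uniform(0, 800, 60)
        d = rng.uniform(10, 700, 60)
        wa = _isotropic_weight_rect(x, y, d, rect)
        wp = _isotropic_weight_poly(x, y, d, box(*rect), quad_segs=256)
        np.testing.assert_allclose(wa, wp, rtol=2e-4)

    def test_translation_rect_vs_polygon(self, rng):
        rect = (0.0, 0.0, 1000.0, 800.0)
        dx = rng.uniform(-600, 600, 60)
        dy = rng.uniform(-500, 500, 60)
        np.testing.assert_allclose(
            _translation_weight_rect(dx, dy, rect),
            _translation_weight_poly(dx, dy, box(*rect)),
            rtol=1e-9,
        )

    def test_interior_pair_weight_is_one(self):
        rect = (0.0, 0.0, 10_000.0, 10_000.0)
        w = _isotropic_weight_rect(np.array([5000.0]), np.array([5000.0]),
                                   np.array([100.0]), rect)
        assert w[0] == pytest.approx(1.0)


def naive_cross_pcf(Xi, Xj, rect, r, bw, correction):
    """Independent O(n^2) reference: explicit double loop over all pairs."""
    xmin, ymin, xmax, ymax = rect
    area = (xmax - xmin) * (ymax - ymin)
    lam_i = len(Xi) / area
    lam_j = len(Xj) / area
    g = np.zeros_like(r)
    for k, rk in enumerate(r):
        total = 0.0
        for u in Xi:
            for v in Xj:
                d = float(np.hypot(*(u - v)))
                if d == 0.0 or abs(rk - d) > bw:
                    continue
                if correction == "translation":
                    e = area / ((xmax - xmin - abs(v[0] - u[0])) * (ymax - ymin - abs(v[1] - u[1])))
                else:
                    e = float(
                        _isotropic_weight_rect(
                            np.array([u[0]]), np.array([u[1]]), np.array([d]), rect
                        )[0]
                    )
                kern = 0.75 / bw * (1.0 - ((rk - d) / bw) ** 2)
                total += kern * e
        g[k] = total / (2.0 * np.pi * rk * lam_i * lam_j * area)
    return g


class TestCrossPcf:
    def test_matches_naive_oracle_both_corrections(self, rng):
        rect = (0.0, 0.0, 2000.0, 2000.0)
        Xi = rng.uniform(0, 2000, (20, 2))
        Xj = rng.uniform(0, 2000, (20, 2))
        r = np.arange(100.0, 1500.0, 100.0)
        c = cross_pcf(Xi, Xj, rect, r=r, bw=150.0)
        np.testing.assert_allclose(
            c.g_iso, naive_cross_pcf(Xi, Xj, rect, r, 150.0, "isotropic"), atol=1e-10
        )
        np.testing.assert_allclose(
            c.g_trans, naive_cross_pcf(Xi, Xj, rect, r, 150.0, "translation"), atol=1e-10
        )

    def test_csr_mean_is_one(self):
        """Two independent Poisson patterns: mean g(r) within 0.1 of 1 (200 reps)."""
        rng = np.random.default_rng(99)
        L = 10_000.0
        r = np.arange(300.0, 2500.0, 200.0)
        acc_iso = np.zeros_like(r)
        acc_tr = np.zeros_like(r)
        reps = 200
        for _ in range(reps):
            Xi = rng.uniform(0, L, (80, 2))
            Xj = rng.uniform(0, L, (80, 2))
            c = cross_pcf(Xi, Xj, (0, 0, L, L), r=r)
            acc_iso += c.g_iso
            acc_tr += c.g_trans
        assert np.abs(acc_iso / reps - 1.0).max() < 0.1
        assert np.abs(acc_tr / reps - 1.0).max() < 0.1

    def test_jittered_pattern_peaks_near_jitter_scale(self):
        """Type-j points displaced by exactly 100 m: g peaks within bw of 100 m."""
        rng = np.random.default_rng(5)
        L = 10_000.0
        Xi = rng.uniform(0, L, (250, 2))
        theta = rng.uniform(0, 2 * np.pi, 250)
        Xj = Xi + 100.0 * np.column_stack([np.cos(theta), np.sin(theta)])
        inside = (Xj[:, 0] >= 0) & (Xj[:, 0] <= L) & (Xj[:, 1] >= 0) & (Xj[:, 1] <= L)
        bw = 40.0
        c = cross_pcf(Xi[inside], Xj[inside], (0, 0, L, L),
                      r=np.arange(20.0, 2000.0, 20.0), bw=bw)
        s = pcf_summary(c, "isotropic", threshold=1.5)
        assert s["peak_g"] > 5.0
        assert abs(s["peak_r"] - 100.0) <= bw
        # decays with distance beyond the peak
        far = c.g_iso[c.r > 500.0]
        assert far.mean() < s["peak_g"] / 3.0

    def test_translation_correction_symmetric_in_i_and_j(self, rng):
        L = 5000.0
        Xi = rng.uniform(0, L, (40, 2))
        Xj = rng.uniform(0, L, (30, 2))
        r = np.arange(200.0, 2000.0, 200.0)
        c1 = cross_pcf(Xi, Xj, (0, 0, L, L), r=r, bw=200.0, corrections=("translation",))
        c2 = cross_pcf(Xj, Xi, (0, 0, L, L), r=r, bw=200.0, corrections=("translation",))
        np.testing.assert_allclose(c1.g_trans, c2.g_trans, rtol=1e-9)

    def test_polygon_window_close_to_rect_formulas(self, rng):
        rect = (0.0, 0.0, 3000.0, 3000.0)
        Xi = rng.uniform(0, 3000, (30, 2))
        Xj = rng.uniform(0, 3000, (30, 2))
        r = np.arange(200.0, 1500.0, 200.0)
        c_rect = cross_pcf(Xi, Xj, rect, r=r, bw=200.0)
        c_poly = cross_pcf(Xi, Xj, box(*rect), r=r, bw=200.0)
        np.testing.assert_allclose(c_poly.g_iso, c_rect.g_iso, rtol=2e-3)
        np.testing.assert_allclose(c_poly.g_trans, c_rect.g_trans, rtol=1e-6)

    def test_empty_pattern_and_zero_r_rejected(self):
        with pytest.raises(ValueError):
            cross_pcf(np.empty((0, 2)), np.ones((5, 2)), (0, 0, 1, 1))
        with pytest.raises(ValueError):
            cross_pcf(np.ones((5, 2)), np.ones((5, 2)), (0, 0, 1, 1), r=np.array([0.0, 1.0]))


class TestPcfSummary:
    def _curve(self, r, g):
        from forage_overlap.overlap import CrossPcfCurve

        return CrossPcfCurve(r=r, g_iso=g, g_trans=None, lambda_i=1.0, lambda_j=1.0,
                             window_area=1.0, bw=1.0)

    def test_flat_curve_no_peak(self):
        r = np.arange(1.0, 10.0)
        s = pcf_summary(self._curve(r, np.ones_like(r)), threshold=1.5)
        assert s["peak_g"] is None

    def test_monotone_decreasing_peaks_at_smallest_r(self):
        r = np.arange(1.0, 10.0)
        s = pcf_summary(self._curve(r, 10.0 / r), threshold=1.5)
        assert s["peak_r"] == 1.0


class TestEstimatorWrapper:
    def test_fit_sets_curve_and_summary(self, rng):
        est = CrossPairCorrelation(window=(0, 0, 5000, 5000),
                                   r=np.arange(200.0, 2000.0, 200.0))
        est.fit(rng.uniform(0, 5000, (30, 2)), rng.uniform(0, 5000, (30, 2)))
        assert est.curve_.g_iso.shape == est.curve_.r.shape
        assert "isotropic" in est.summary_

    def test_epanechnikov_integrates_to_one(self):
        t = np.linspace(-200.0, 200.0, 4001)
        k = _epanechnikov(t, 120.0)
        assert np.trapezoid(k, t) == pytest.approx(1.0, abs=1e-6)
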