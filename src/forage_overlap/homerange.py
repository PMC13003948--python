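"""Kernel utilisation distributions, plug-in bandwidths and probability isopleths.

The utilisation distribution (UD) is a bivariate Gaussian kernel density on
a regular grid in the local projection.  The bandwidth matrix is selected by
a two-stage unconstrained plug-in of the Wand–Jones family: the data are
sphered, integrated density-derivative functionals of order six are
estimated with normal-reference pilots (order eight), those feed the pilots
for the order-four functionals, and the asymptotic MISE

    PI(H) = (4*pi*n)^-1 |H|^-1/2 + psi(H)/4

is minimised over symmetric positive-definite H (Cholesky parametrised),
then back-transformed.  Sphering makes the selector exactly affine
equivariant.

X% isopleths are highest-density regions: cells are ranked by density and
accumulated until they hold X% of the mass; the resulting density threshold
is contoured with marching squares (linear interpolation).  Land and
regulatory zones are erased *after* contouring and *before* geodesic area
measurement, and the remaining mass is deliberately not renormalised.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cholesky, solve_triangular
from scipy.optimize import minimize
from shapely.geometry import MultiPolygon, Polygon
from shapely.ops import unary_union
from skimage import measure
from sklearn.base import BaseEstimator

from .geodesy import LocalProjection, geodesic_area_km2
from .io import CoastGeometry, logger

__all__ = [
    "BandwidthError", "UtilisationDistribution", "IsoplethPolygon", "PlaneContour",
    "plugin_bandwidth", "normal_scale_bandwidth", "evaluate_kde", "volume_contours",
    "contours_to_geo", "erase_excluded", "KernelHomeRange",
]


class BandwidthError(ValueError):
    """Degenerate point configuration for bandwidth selection."""


# ---------------------------------------------------------------------------
# Plug-in bandwidth


def _hermite(k: int, t: np.ndarray) -> np.ndarray:
    if k == 0:
        return np.ones_like(t)
    if k == 1:
        return t
    hm2, hm1 = np.ones_like(t), t
    for j in range(2, k + 1):
        hm2, hm1 = hm1, t * hm1 - (j - 1) * hm2
    return hm1


_SQRT2PI = np.sqrt(2.0 * np.pi)


def _phi_deriv(k: int, u: np.ndarray, g: float) -> np.ndarray:
    """k-th derivative of the N(0, g^2) density evaluated at u."""
    t = u / g
    return (-1.0) ** k * g ** (-(k + 1)) * _hermite(k, t) * np.exp(-0.5 * t * t) / _SQRT2PI


def _phi_deriv0(k: int, sigma: float) -> float:
    """k-th derivative of the N(0, sigma^2) density at 0 (0 for odd k)."""
    if k % 2 == 1:
        return 0.0
    m = k // 2
    dfact = 1.0
    for j in range(1, k, 2):
        dfact *= j
    return (-1.0) ** m * dfact * sigma ** (-(k + 1)) / _SQRT2PI


def _psi_normal_ref(r: tuple[int, int]) -> float:
    """Integrated density-derivative functional of N(0, I): psi_r = D^r phi_{2I}(0)."""
    return _phi_deriv0(r[0], np.sqrt(2.0)) * _phi_deriv0(r[1], np.sqrt(2.0))


def _psi_hat(Z: np.ndarray, r: tuple[int, int], g: float) -> float:
    """Kernel estimate of psi_r with scalar pilot g (includes i = j pairs)."""
    n = Z.shape[0]
    total = 0.0
    block = max(1, int(4e6 / n))  # bound peak memory for large n
    for s in range(0, n, block):
        dx = Z[s : s + block, 0][:, None] - Z[:, 0][None, :]
        dy = Z[s : s + block, 1][:, None] - Z[:, 1][None, :]
        total += float((_phi_deriv(r[0], dx, g) * _phi_deriv(r[1], dy, g)).sum())
    return total / (n * n)


def _even_pilot(r: tuple[int, int], psi_next: dict, n: int) -> float:
    """AMSE-optimal scalar pilot for estimating psi_r (even components)."""
    num = 2.0 * abs(_phi_deriv0(r[0], 1.0) * _phi_deriv0(r[1], 1.0))
    den = n * abs(
        psi_next[(r[0] + 2, r[1])] + psi_next[(r[0], r[1] + 2)]
    )
    expo = 1.0 / (2 + sum(r) + 2)  # d + |r| + 2
    return (num / max(den, 1e-300)) ** expo


def _pilots_for_order(order: int, psi_next: dict, n: int) -> dict:
    """Pilots for all psi_r with |r| = order; odd-component r borrow from neighbours."""
    rs = [(order - k, k) for k in range(order + 1)]
    out = {}
    for r in rs:
        if r[0] % 2 == 0 and r[1] % 2 == 0:
            out[r] = _even_pilot(r, psi_next, n)
    even_gs = list(out.values())
    gmean = float(np.exp(np.mean(np.log(even_gs)))) if even_gs else n ** (-1.0 / (order + 4))
    for r in rs:
        if r not in out:
            out[r] = gmean
    return out


def normal_scale_bandwidth(points: np.ndarray) -> np.ndarray:
    """Gaussian reference bandwidth H_NS = (4/(d+2))^(2/(d+4)) n^(-2/(d+4)) S, d = 2."""
    X = np.asarray(points, dtype=float)
    n = X.shape[0]
    return (4.0 / 4.0) ** 0 * (4.0 / (2 + 2)) ** (2.0 / 6.0) * n ** (-1.0 / 3.0) * np.cov(X.T)


def plugin_bandwidth(points: np.ndarray) -> np.ndarray:
    """Two-stage unconstrained plug-in bandwidth matrix (m² in the projection).

    Requires at least 8 non-collinear points; below that, raises
    :class:`BandwidthError` recommending :func:`normal_scale_bandwidth`.
    """
    X = np.asarray(points, dtype=float)
    if X.ndim != 2 or X.shape[1] != 2:
        raise ValueError("points must be (n, 2)")
    n = X.shape[0]
    if n < 8:
        raise BandwidthError(
            "plug-in selection needs >= 8 points; use normal_scale_bandwidth instead"
        )
    S = np.cov(X.T)
    evals = np.linalg.eigvalsh(S)
    if evals[0] <= 1e-10 * max(evals[-1], 1e-300):
        raise BandwidthError("points are (near-)collinear; bandwidth matrix is degenerate")

    L = cholesky(S, lower=True)
    Z = solve_triangular(L, (X - X.mean(axis=0)).T, lower=True).T

    # stage 1: psi_6 with pilots from the order-8 normal reference
    psi8 = {r: _psi_normal_ref(r) for r in [(8 - k, k) for k in range(9)]}
    g6 = _pilots_for_order(6, psi8, n)
    psi6 = {r: _psi_hat(Z, r, g6[r]) for r in [(6 - k, k) for k in range(7)]}
    # stage 2: psi_4 with pilots from the estimated psi_6
    g4 = _pilots_for_order(4, psi6, n)
    psi4 = {r: _psi_hat(Z, r, g4[r]) for r in [(4 - k, k) for k in range(5)]}

    def theta(H):
        h11, h12, h22 = H[0, 0], H[0, 1], H[1, 1]
        return (
            h11 * h11 * psi4[(4, 0)]
            + h22 * h22 * psi4[(0, 4)]
            + (4.0 * h12 * h12 + 2.0 * h11 * h22) * psi4[(2, 2)]
            + 4.0 * h11 * h12 * psi4[(3, 1)]
            + 4.0 * h12 * h22 * psi4[(1, 3)]
        )

    def objective(p):
        a, b, c = p
        Lh = np.array([[np.exp(a), 0.0], [b, np.exp(c)]])
        H = Lh @ Lh.T
        det = H[0, 0] * H[1, 1] - H[0, 1] ** 2
        return 1.0 / (4.0 * np.pi * n * np.sqrt(det)) + 0.25 * theta(H)

    h0 = (4.0 / 4.0) * (2.0 / 3.0) ** (1.0 / 3.0) * n ** (-1.0 / 3.0)
    x0 = np.array([0.5 * np.log(h0), 0.0, 0.5 * np.log(h0)])
    res = minimize(objective, x0, method="Nelder-Mead",
                   options={"xatol": 1e-8, "fatol": 1e-12, "maxiter": 2000})
    a, b, c = res.x
    Lh = np.array([[np.exp(a), 0.0], [b, np.exp(c)]])
    H_z = Lh @ Lh.T
    return L @ H_z @ L.T


# ---------------------------------------------------------------------------
# KDE on a grid


@dataclass
class UtilisationDistribution:
    """Gridded KDE surface in the local projection (density in m^-2).

    ``x0``/``y0`` are the coordinates of the centre of cell (0, 0); cell
    (iy, ix) has centre (x0 + ix*cell_m, y0 + iy*cell_m).  The density is
    renormalised over the grid so that sum(density) * cell area = 1.
    """

    x0: float
    y0: float
    cell_m: float
    density: np.ndarray          # (ny, nx)
    n_points: int
    bandwidth: np.ndarray
    coverage: float = 1.0        # grid mass before renormalisation

    @property
    def nx(self) -> int:
        return self.density.shape[1]

    @property
    def ny(self) -> int:
        return self.density.shape[0]

    def total_mass(self) -> float:
        return float(self.density.sum() * self.cell_m**2)

    def mass_above(self, threshold: float) -> float:
        d = self.density
        return float(d[d >= threshold].sum() * self.cell_m**2)


def evaluate_kde(
    points: np.ndarray,
    H: np.ndarray,
    cell_m: float = 250.0,
    margin_sigmas: float = 3.0,
    bounds: tuple[float, float, float, float] | None = None,
    min_coverage: float = 0.999,
) -> UtilisationDistribution:
    """Evaluate the Gaussian-kernel UD at cell centres and renormalise.

    The grid is the point bounding box padded by ``margin_sigmas`` times the
    largest bandwidth s.d. (or explicit ``bounds``); if it captures less than
    ``min_coverage`` of the total kernel mass an error is raised rather than
    silently truncating.
    """
    X = np.asarray(points, dtype=float)
    H = np.asarray(H, dtype=float)
    if X.ndim != 2 or X.shape[1] != 2 or X.shape[0] == 0:
        raise ValueError("points must be a non-empty (n, 2) array")
    evals = np.linalg.eigvalsh(H)
    if evals[0] <= 0:
        raise ValueError("bandwidth matrix must be positive definite")
    pad = margin_sigmas * np.sqrt(evals[-1])
    if bounds is None:
        xmin, ymin = X.min(axis=0) - pad
        xmax, ymax = X.max(axis=0) + pad
    else:
        xmin, ymin, xmax, ymax = bounds
    nx = max(2, int(np.ceil((xmax - xmin) / cell_m)) + 1)
    ny = max(2, int(np.ceil((ymax - ymin) / cell_m)) + 1)
    gx = xmin + cell_m * np.arange(nx)
    gy = ymin + cell_m * np.arange(ny)

    Hinv = np.linalg.inv(H)
    norm = 1.0 / (2.0 * np.pi * np.sqrt(np.linalg.det(H)))
    density = np.zeros((ny, nx))
    # accumulate kernels in manageable chunks of points
    chunk = max(1, int(2e7 / (nx * ny))) if nx * ny else 1
    GX, GY = np.meshgrid(gx, gy)
    for s in range(0, X.shape[0], chunk):
        P = X[s : s + chunk]
        dx = GX[None, :, :] - P[:, 0, None, None]
        dy = GY[None, :, :] - P[:, 1, None, None]
        q = (
            Hinv[0, 0] * dx * dx + 2.0 * Hinv[0, 1] * dx * dy + Hinv[1, 1] * dy * dy
        )
        density += norm * np.exp(-0.5 * q).sum(axis=0)
    density /= X.shape[0]

    coverage = float(density.sum() * cell_m**2)
    if coverage < min_coverage:
        raise ValueError(
            f"grid captures only {coverage:.4f} of the kernel mass; enlarge the "
            "grid or the margin"
        )
    density /= coverage
    return UtilisationDistribution(
        x0=float(gx[0]), y0=float(gy[0]), cell_m=cell_m, density=density,
        n_points=X.shape[0], bandwidth=H, coverage=coverage,
    )


# ---------------------------------------------------------------------------
# Isopleths


@dataclass
class PlaneContour:
    """An isopleth in the projected plane, before geographic conversion."""

    level: float
    threshold: float            # density threshold t_L (m^-2)
    geometry: MultiPolygon      # projected metres
    area_m2: float
    cell_mass: float            # mass of grid cells with density >= t_L


@dataclass
class IsoplethPolygon:
    """A probability contour in lon/lat with pre- and post-erase geodesic areas."""

    level: float
    geometry: MultiPolygon
    pre_erase_area_km2: float
    area_km2: float
    threshold: float = field(default=np.nan)


def _rings_to_multipolygon(rings: list[np.ndarray]) -> MultiPolygon:
    polys = [Polygon(r) for r in rings if len(r) >= 4]
    polys = [p if p.is_valid else p.buffer(0) for p in polys]
    polys = [p for p in polys if not p.is_empty and p.area > 0]
    if not polys:
        return MultiPolygon([])
    # nesting depth decides shell vs hole
    depth = []
    for i, p in enumerate(polys):
        rep = p.representative_point()
        depth.append(sum(1 for j, q in enumerate(polys) if j != i and q.contains(rep)))
    shells = [i for i, d in enumerate(depth) if d % 2 == 0]
    holes_of: dict[int, list[int]] = {i: [] for i in shells}
    for i, d in enumerate(depth):
        if d % 2 == 1:
            parents = [
                j for j in shells
                if polys[j].contains(polys[i].representative_point()) and depth[j] == d - 1
            ]
            if parents:
                parent = min(parents, key=lambda j: polys[j].area)
                holes_of[parent].append(i)
    out = []
    for j in shells:
        out.append(
            Polygon(
                polys[j].exterior.coords,
                [polys[k].exterior.coords for k in holes_of[j]],
            )
        )
    geom = unary_union(out)
    if geom.geom_type == "Polygon":
        geom = MultiPolygon([geom])
    return geom


def volume_contours(
    ud: UtilisationDistribution, levels: tuple[float, ...] = (0.5, 0.75, 0.95)
) -> list[PlaneContour]:
    """Extract highest-density-region contours holding each probability level.

    The threshold t_L is the density of the last cell needed to accumulate a
    mass >= L (ties included); the t_L iso-line is traced by marching squares
    with linear interpolation on a zero-padded copy of the grid so contours
    always close.
    """
    for lv in levels:
        if not 0.0 < lv < 1.0:
            raise ValueError(f"isopleth level must be in (0, 1), got {lv}")
    cell_area = ud.cell_m**2
    flat = np.sort(ud.density.ravel())[::-1]
    cum = np.cumsum(flat) * cell_area
    padded = np.pad(ud.density, 1, mode="constant")
    out = []
    for lv in sorted(levels):
        k = int(np.searchsorted(cum, lv))
        k = min(k, flat.size - 1)
        t = flat[k]
        trace_level = t * (1.0 - 1e-9)
        rings = measure.find_contours(padded, trace_level)
        rings_xy = [
            np.column_stack(
                [ud.x0 + (r[:, 1] - 1.0) * ud.cell_m, ud.y0 + (r[:, 0] - 1.0) * ud.cell_m]
            )
            for r in rings
        ]
        geom = _rings_to_multipolygon(rings_xy)
        out.append(
            PlaneContour(
                level=float(lv), threshold=float(t), geometry=geom,
                area_m2=float(geom.area), cell_mass=ud.mass_above(t),
            )
        )
    return out


def contours_to_geo(
    contours: list[PlaneContour], projection: LocalProjection
) -> list[IsoplethPolygon]:
    """Convert plane contours to lon/lat isopleths with geodesic areas."""
    out = []
    for c in contours:
        geom = projection.unproject_geom(c.geometry)
        if geom.geom_type == "Polygon":
            geom = MultiPolygon([geom])
        area = geodesic_area_km2(geom)
        out.append(
            IsoplethPolygon(
                level=c.level, geometry=geom, pre_erase_area_km2=area,
                area_km2=area, threshold=c.threshold,
            )
        )
    return out


def erase_excluded(
    isopleths: list[IsoplethPolygon],
    coast: CoastGeometry,
    zones: tuple[str, ...] = ("mainland", "island"),
) -> list[IsoplethPolygon]:
    """Set-difference each isopleth against named zones, then re-measure.

    Penguin UDs erase land only (``mainland``, ``island``); fishery UDs add
    ``exclusion_1nm``.  Mass is *not* renormalised afterwards: areas are
    reported for the clipped polygons as-is.
    """
    eraser_parts = []
    for z in zones:
        eraser_parts.append(getattr(coast, z))
    eraser = unary_union(eraser_parts)
    out = []
    for iso in isopleths:
        clipped = iso.geometry.difference(eraser)
        if not clipped.is_valid:
            logger.warning("repairing invalid geometry after erase (level %.2f)", iso.level)
            clipped = clipped.buffer(0)
        if clipped.geom_type == "Polygon":
            clipped = MultiPolygon([clipped]) if not clipped.is_empty else MultiPolygon([])
        elif clipped.geom_type == "GeometryCollection":
            polys = [g for g in clipped.geoms if g.geom_type in ("Polygon", "MultiPolygon")]
            clipped = unary_union(polys)
            if clipped.geom_type == "Polygon":
                clipped = MultiPolygon([clipped])
        out.append(
            IsoplethPolygon(
                level=iso.level, geometry=clipped,
                pre_erase_area_km2=iso.pre_erase_area_km2,
                area_km2=geodesic_area_km2(clipped),
                threshold=iso.threshold,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Estimator


class KernelHomeRange(BaseEstimator):
    """Kernel utilisation distribution with plug-in bandwidth and HDR isopleths.

    Parameters
    ----------
    cell_m : grid cell size in metres (default 250).
    levels : probability levels of the isopleths.
    bandwidth : fixed 2x2 bandwidth matrix; None selects the two-stage
        plug-in (:func:`plugin_bandwidth`).
    margin_sigmas : grid padding in units of the largest kernel s.d.
    bounds : optional explicit grid bounds (xmin, ymin, xmax, ymax).

    Attributes (after ``fit(X)`` with X = (n, 2) projected metres)
    ----------
    bandwidth_ : selected or given bandwidth matrix (m²).
    ud_ : the gridded :class:`UtilisationDistribution`.
    contours_ : list of :class:`PlaneContour`, ordered by level.
    """

    def __init__(self, cell_m: float = 250.0, levels: tuple = (0.5, 0.75, 0.95),
                 bandwidth=None, margin_sigmas: float = 3.0, bounds=None):
        self.cell_m = cell_m
        self.levels = levels
        self.bandwidth = bandwidth
        self.margin_sigmas = margin_sigmas
        self.bounds = bounds

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        H = np.asarray(self.bandwidth, dtype=float) if self.bandwidth is not None else plugin_bandwidth(X)
        self.bandwidth_ = H
        self.ud_ = evaluate_kde(
            X, H, cell_m=self.cell_m, margin_sigmas=self.margin_sigmas, bounds=self.bounds
        )
        self.contours_ = volume_contours(self.ud_, tuple(self.levels))
        self.n_features_in_ = 2
        return self

    def score_samples(self, X) -> np.ndarray:
        """Log-density at arbitrary points, read off the fitted grid."""
        X = np.asarray(X, dtype=float)
        # nearest-cell lookup on the fitted grid
        ix = np.clip(np.rint((X[:, 0] - self.ud_.x0) / self.ud_.cell_m).astype(int), 0, self.ud_.nx - 1)
        iy = np.clip(np.rint((X[:, 1] - self.ud_.y0) / self.ud_.cell_m).astype(int), 0, self.ud_.ny - 1)
        return np.log(np.maximum(self.ud_.density[iy, ix], 1e-300))

    def isopleths(self, projection: LocalProjection) -> list[IsoplethPolygon]:
        """Fitted contours as lon/lat isopleths with geodesic areas."""
        return contours_to_geo(self.contours_, projection)
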