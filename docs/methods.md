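# Methods

This note documents the models, defaults and numerical choices behind the
package, and what the synthetic study system does and does not emulate.

## Geodesy without a projection library

All geographic primitives are implemented in-package on the WGS84 ellipsoid:

* **Distance / bearing** — Vincenty's inverse formulae (sub-mm convergence
  at the ≤ 100 km scales involved; near-antipodal pairs, where the
  iteration can fail, cannot occur here).
* **Polygon area** — geodetic latitude is mapped to authalic latitude (an
  exactly area-preserving change of variable), and the polygon is measured
  on the authalic sphere through a Lambert azimuthal equal-area projection
  centred on the polygon. Against the closed-form latitude-band integral
  for lon/lat rectangles the error is < 0.01%; polygon edges are treated as
  straight in the equal-area plane, negligible for densely-vertexed
  contours.
* **Working plane** — a transverse Mercator on the Gauss conformal sphere
  (conformal latitude, Gaussian mean radius at the colony, scale normalised
  to 1 at the origin). Distance distortion over the 62 km analysis window
  is below 0.01%; the tests assert < 0.1% against Vincenty. Kernel grids
  and point-process distances live in this plane; trip distances and all
  reported areas are computed on the ellipsoid instead.

## Dive detection and linking

A dive is a maximal run of consecutive 1 Hz samples with depth ≥ 0.1 m and
length ≥ 5 samples; duration is run length / rate, and max/mean depth are
taken over the run. Gaps (NaN samples) conservatively break runs. No
zero-offset drift correction is applied — the logger noise model keeps
surface readings near zero — but `DiveDetector(preprocess=...)` accepts any
grid-preserving depth correction.

`n` dives partition the record into `n + 1` surface intervals (leading and
trailing included). Fixes timestamped inside a dive are physically
implausible and are dropped with a logged count. Each dive receives the
temporally last fix of its preceding interval, or stays unlocated.

One detection property worth noting: the dive *count* is monotone in the
duration threshold but **not** in the depth threshold — lowering it can
merge two dives across a shallow saddle. What is monotone in both is the
set of samples covered by dives; the property tests check exactly that.

## Trips, centroids and exclusions

* Near-shore positions within 100 m of the island coastline are removed
  before any spatial analysis (shoreline-geometry/GPS-jitter artefacts).
* Trip delimitation is not uniquely defined by the data model; the package
  splits a bird's located dives where consecutive dives are more than
  `gap_h = 4 h` apart (such gaps coincide with colony visits in this
  system). Trips shorter than 2 h, or with fewer than 2 located fixes, are
  flagged excluded, not dropped.
* Trip metrics: duration (first dive start to last dive end), maximum
  geodesic distance from the nest, cumulative distance over consecutive
  dive-linked fixes, and the circular mean (atan2 of mean sine/cosine) of
  nest-to-fix bearings.
* Hourly centroids are means in the working plane per bird × local calendar
  date × hour (UTC−4). Calendar-hour binning, rather than hour-of-day
  pooled across days, is the only reading that yields hundreds of centroids
  from ~21 birds; pooled binning would cap the count at 24 per bird.

## Kernel utilisation distributions

Density: f̂(x) = n⁻¹ Σᵢ φ_H(x − xᵢ) at the centres of a 250 m grid (cell
size configurable), extent = point bounding box padded by 3 bandwidth s.d.;
the evaluation errors out rather than truncating if the grid captures
< 99.9% of the kernel mass, then renormalises to exactly 1.

**Bandwidth.** The two-stage unconstrained plug-in of the Wand–Jones family:
sphere the data by the Cholesky factor of the sample covariance (this makes
the selector exactly affine equivariant); estimate the order-6 integrated
density-derivative functionals ψ_r with AMSE-optimal scalar pilots derived
from the order-8 normal reference; use those to set pilots for the order-4
functionals; minimise PI(H) = (4πn)⁻¹|H|⁻¹ᐟ² + ψ(H)/4 over
Cholesky-parametrised SPD matrices (Nelder–Mead from the normal-scale
start); back-transform. For the odd-order functionals ψ₃₁/ψ₁₃ the pilot
formula degenerates (the Gaussian derivative at zero vanishes), so they
borrow the geometric mean of the even-order pilots — on sphered data these
functionals are near zero and the choice is immaterial. Below 8 points, or
for (near-)collinear configurations, selection refuses and recommends the
normal-scale rule, which is also exported.

**Isopleths.** The X% isopleth is the highest-density region: cells are
ranked by density and accumulated until their mass reaches X%; the density
of the last cell needed is the threshold t_L (ties included —
deterministic and conservative), and the t_L iso-line is traced by marching
squares with linear interpolation on a zero-padded grid so every contour
closes. Ring nesting depth decides shells vs holes.

**Pooling contract.** The forager UD is fitted once on autumn + spring
hourly centroids pooled (the seasonal deployments under-sample the
shoreward nests in autumn; pooling preserves the colony's coastal
component). Fishery UDs are fitted per season, each with its own plug-in
bandwidth — bandwidths are never shared across fits.

**Erasing.** Forager isopleths have the mainland and island erased; fishery
isopleths additionally lose the 1-nautical-mile (1,852 m) exclusion band.
Erasure happens *after* contouring and *before* geodesic area measurement,
and the UD mass is deliberately **not** renormalised afterwards — areas
describe the clipped polygons as-is. Invalid geometries after the
difference are repaired by a zero-buffer and logged.

## Overlap and the cross-PCF

Overlap intersects same-level isopleths; the relative figure is
100 × overlap / forager-isopleth-area, optionally after restricting the
forager isopleth to a sub-polygon (e.g. its coastal core; the pipeline uses
the part within 10 km of the mainland). The delineation of a "coastal core"
has no canonical rule; any user-supplied polygon is accepted and its area
reported.

The cross-PCF estimator follows the kernel form given in the package
docstring with an Epanechnikov kernel and Stoyan's bandwidth
bw = 0.15/√λ_j by default; the r grid is 100 m – 10 km in 100 m steps
(r = 0 is excluded — the estimator carries a 1/r factor). Edge
corrections: translation weight |W| / |W ∩ W_shift|, and Ripley's isotropic
weight, the reciprocal fraction of the circle through the pair centred on
the type-i point that lies inside W. Rectangular windows use exact closed
forms (arc-overlap corner logic), arbitrary polygon windows use geometric
computations on the window itself; both paths are cross-validated in the
tests and the isotropic fraction is floored at 10⁻⁶ to keep weights finite.
The analysis window is the 62 km buffer minus land — the study-area
geometry offers no other natural choice.

## Season models

log(response) ~ season + (1 | bird), fitted by REML (statsmodels MixedLM,
with gradient-free optimizer fallbacks near the variance boundary). Season
varies *between* birds in this design, so Wald inference uses
containment-style degrees of freedom, n_birds − 2; for a between-cluster
factor this is near-exact and, unlike a plain z test, holds the type-I
error at its nominal level in the calibration tests (0.03–0.07 at
α = 0.05 over 500 null replicates). A random-intercept variance estimated
at zero is reported as a singular fit, not an error. The per-trip "home
range" response is the 95% isopleth area of a per-trip KDE on that trip's
located dives (normal-scale bandwidth with a 100 m floor when the plug-in
refuses); trips with < 3 located fixes get no home range.

## The synthetic study system

Defaults are the study conditions: 8 autumn + 13 spring birds, east-nest
probabilities 3/8 and 5/13, deployments uniform on 1–8 days (mean 4.5),
GPS cadence 60 s by day (07:00–19:00 local, fixed clock window) and 900 s
at night, 54 autumn / 43 spring fishing sets, a 6.5 km island–mainland
channel, 1 nm exclusion band, 62 km buffer.

Generator choices where the study reports no mechanism:

* **Movement** — a correlated random walk (persistence 0.7, 1.8 m s⁻¹,
  30 s steps) attracted to a per-trip target, then back to the nest;
  east-side birds target the mainland coastal strip, west-side birds go
  offshore (SW–W, 8–22 km) with probability 0.7 and divert to the coast
  otherwise, rounding the island's southern tip. Steps onto land are
  rejected. This is the simplest generator that reproduces the bimodal
  east/west pattern.
* **Dives** — alternating dive/surface cycles through the daylight part of
  each trip. Depth is a two-part mixture with P(depth ≤ 30 m) = 0.725 by
  construction (Beta-shaped below 30 m, truncated exponential above, range
  0.5–110 m); duration ≈ 16 s + 1.3 s·m⁻¹ × depth (clipped 6–180 s).
* **GPS dropout** — P(no fix in a surface interval of length s) =
  exp(−s/τ), τ = 120 s, realised as a Poisson acquisition process thinned
  to the 1-min cadence. Surface intervals are lognormal; their median
  (55 s, σ = 0.9) was set so the expected located-dive fraction is ≈ 0.41,
  the study's yield (11,733/28,930 ≈ 0.406). Fix noise is 15 m, resampled
  if it lands a fix ashore.
* **Sensors** — surface noise N(0, 0.02 m) clipped at ±4σ so noise alone
  can never cross the 0.1 m threshold; dive profiles are trapezoids floored
  at 0.45 m. Consequently detection recovers the planted schedule
  bit-exactly, which is what makes the oracle tests sharp.
* **Fishery** — a Thomas cluster process (Poisson parents in a seasonal
  box, Poisson offspring, Gaussian scatter: autumn σ = 1.5 km inshore,
  spring σ = 4 km south/offshore), rejected onto legal water and resampled
  to the exact seasonal counts. The clustered-pattern family is a modelling
  choice; only the maps' qualitative structure is known.

What it does **not** emulate: prey fields and environmental covariates
(SST/chl-a), behavioural states within trips, accelerometry, tag effects,
bathymetry, or per-set catch magnitudes. Passing tests therefore validate
the *pipeline* — detection, linking, geometry, estimators — not ecological
realism, and headline areas from the synthetic colony are not expected to
equal the field study's numbers. At the default scale the colony yields
roughly 13–14k dives (about half the field count: the generator dives only
in daylight at ~30 dives h⁻¹) and ~500 hourly centroids; these sizes keep a
full run around half a minute while leaving every statistic well away from
small-sample degeneracy.

## Known limitations

* The isotropic-correction weight for polygon windows discretises the
  circle through the window boundary (shapely buffer, 96 segments/quadrant);
  error is ~10⁻⁴ relative, far below estimator noise.
* `score_samples` on `KernelHomeRange` reads the fitted grid
  (nearest-cell), not the exact kernel sum.
* The reported spring-fishery 50% area in the source material is internally
  inconsistent (62.1 km² in its summary table vs 483.6 km² in its text);
  the pipeline simply reports its own computed value and takes no side.
* Mixed-model p-values use containment df, not Satterthwaite; for this
  between-bird design the two are nearly identical, and the Monte-Carlo
  calibration is the authoritative check.
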