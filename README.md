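# forage-overlap

Quantifying spatio-temporal overlap between breeding central-place foragers
(Humboldt penguins tracked with archival GPS dive loggers) and purse-seine
fishing effort. The package takes raw 1 Hz depth traces and duty-cycled GPS
fixes through the full analysis chain:

1. **Dive detection** — dives are maximal runs of depth ≥ 0.1 m lasting
   ≥ 5 s; the gaps between dives are surface intervals.
2. **Dive–fix linking** — each dive inherits the *last* GPS fix of its
   immediately preceding surface interval (birds cannot acquire satellites
   underwater, so every usable position is a surface position).
3. **Trips and centroids** — near-shore fixes (≤ 100 m from the island) are
   excluded; located dives are segmented into foraging trips with duration,
   maximum nest distance, cumulative track length and mean bearing; positions
   are aggregated to hourly centroids per bird to even out sampling.
4. **Kernel home ranges** — a bivariate Gaussian-kernel utilisation
   distribution (UD) is fitted to the pooled centroids, with the bandwidth
   matrix **H** chosen by a two-stage unconstrained plug-in selector
   (Wand–Jones family, as in `ks::Hpi`). 50/75/95% probability isopleths are
   the smallest regions holding that share of the UD mass; land (and for
   fishery UDs the 1-nautical-mile exclusion band) is erased before areas
   are measured geodesically on the WGS84 ellipsoid.
5. **Overlap and spatial association** — matching isopleths are intersected
   (absolute km² and % of the forager's area), and the cross-type pair
   correlation function

   g<sub>ij</sub>(r) = Σ<sub>u∈i</sub> Σ<sub>v∈j</sub> κ<sub>bw</sub>(r − ‖u−v‖) e(u,v) / (2πr λ<sub>i</sub> λ<sub>j</sub> |W|)

   is estimated with both Ripley's isotropic and the translation edge
   correction; g = 1 means independence, g > 1 co-occurrence.
6. **Seasonal models** — trip metrics are compared between seasons with
   random-intercept mixed models on log responses (REML), one intercept per
   bird.

Because the original tracking and fishery data are not public, the package
ships a ground-truthed **synthetic colony generator** (`simulate` module)
that emulates the study system — two seasons with 8 + 13 birds, 1–8 day
deployments, east/west nest-side departure asymmetry, a dive-depth mixture
with 72.5% of dives in the upper 30 m, surface-interval-dependent GPS
dropout yielding ~40% located dives, and Thomas-cluster fishing sets
(inshore in autumn, dispersed/southward in spring). Every downstream stage
is tested against the generator's truth.

Audience: movement ecologists and fisheries scientists who want a tested,
scriptable version of this analysis (or its pieces: dive detection, plug-in
KDE home ranges, cross-PCF) without ArcGIS/R round-trips.

## Worked example

```python
from forage_overlap import run_pipeline

res = run_pipeline(seed=1)          # full synthetic colony, ~30 s
print(res.counts)
for iso in res.penguin_isopleths:
    print(iso.level, round(iso.area_km2, 1))
print(res.pcf["autumn"]["summary"]["isotropic"])
```

prints

```
{'n_birds': 21, 'n_trips': 46, 'n_trips_excluded': 1, 'n_dives': 13423,
 'n_dives_linked': 5547, 'located_fraction': 0.413, 'pct_dives_le_30m': 72.76,
 'n_hourly_centroids': 493, 'n_sets_autumn': 54, 'n_sets_spring': 43}
0.5 87.6
0.75 193.4
0.95 401.6
{'peak_g': 110.0, 'peak_r': 100.0, 'r_above': (100.0, 10000.0)}
```

Read: 21 tracked birds produced 13,423 dives of which 41.3% acquired a
linked GPS fix (the field study's yield was 40.6%); 72.8% of dives stayed in
the upper 30 m. The pooled colony's core area (50% isopleth, after erasing
land) is 87.6 km². Autumn fishing sets cluster on the birds' coastal
foraging ground — the cross-PCF rises far above 1 at short range — while
the spring overlap is zero everywhere (see `res.overlap_table()`).

The same run is available from the shell:

```bash
forage-overlap run --seed 1 --outdir out/         # all products as CSV/GeoJSON/JSON
forage-overlap simulate --outdir synthetic_data/  # raw logger + fishery CSVs
forage-overlap dives synthetic_data/logger.csv    # single stage
```

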