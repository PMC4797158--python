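# riparia

Movement ecology and habitat suitability for riparian birds, as one tested
pipeline: paired-observer radio-tracking bearings → triangulated fixes →
home ranges → habitat preference and movement behaviour → a random-walk
null model for site fidelity → chained maxent-style habitat-suitability
maps from multispectral imagery.

The package targets the study system of East African river valleys where
the invasive shrub *Lantana camara* has replaced much of the indigenous
riparian thicket and now serves as surrogate habitat for thicket birds.
Because field telemetry of this kind is rarely deposited, the package ships
a synthetic-data generator that reproduces the statistical structure of
such a study — a river-hugging thicket mosaic, class-conditional band
reflectances, and habitat-selecting correlated-random-walk tracks fixed
every 10 min — so every stage is testable end to end.

## Methods at a glance

* **Triangulation** — a fix is the intersection of the two forward bearing
  rays; fixes > 1000 m from either observer are discarded.
* **Home ranges** — MCP95 (convex hull of the 95% of fixes nearest the
  centroid) and kernel utilization distributions with the normal-reference
  bandwidth `h_ref = sqrt((var x + var y)/2) · n^(−1/6)`; K95/K75/K50
  isopleths by descending-density cell accumulation.
* **Habitat preference** — Jacobs selectivity
  `D = (r − p)/(r + p − 2rp)` from used (core-area K75 ∩ land cover) and
  available fractions, tested per habitat with the exact sign test.
* **Movement** — step distances in m·10 min⁻¹ attributed to the habitat of
  the step's start fix; one-way ANOVA (log(x+1) on Shapiro–Wilk rejection)
  between species.
* **Site fidelity** — 1000 bootstrap random walks resampling the observed
  step lengths and turning angles; fidelity when the observed range falls
  below the null's 95% CI.
* **Suitability** — L1-regularized Gibbs (maximum-entropy) density over
  background cells with linear/quadratic/product features; a
  distance-to-river pre-model thresholded at the 10-percentile training
  omission becomes a spatial mask; a spectral *L. camara* sub-model on
  seven vegetation indices (NDVI, GNDVI, NDRE, GCM, GRM, RENDVI, REGNDVI)
  feeds the final per-species models, evaluated over 10 random 70/30
  presence splits by ranked AUC.

## Worked example

```python
import numpy as np
import riparia as rp
from shapely.geometry import box

lc = rp.generate_landscape(rp.LandscapeSpec(seed=1))
pref = {"lantana": 1.0, "mixed": 0.2, "indigenous": 0.2,
        "crops_low": 0.1, "crops_high": 0.05, "settlement": 0.01}
track = rp.generate_track(lc, rp.MovementSpec(
    n_fixes=500, river_attraction=0.2, habitat_preference=pref, seed=3))

mcp95 = rp.mcp(track)
h = rp.href_bandwidth(track)
ud = rp.kernel_ud(track, h=h)
k95 = rp.ud_contour(ud, 0.95, polygonize=False)
k75 = rp.ud_contour(ud, 0.75)
print(f"href = {h:.1f} m")
print(f"MCP95 = {mcp95.area_ha:.2f} ha, K95 = {k95.area_ha:.2f} ha, K75 = {k75.area_ha:.2f} ha")

avail, _ = rp.habitat_fractions(box(*lc.extent), lc)
used, _ = rp.habitat_fractions(k75.polygon, lc)
for cls in ("lantana", "crops_high"):
    D = rp.jacobs_index(used.get(cls, 0.0), avail[cls])
    print(f"Jacobs D({cls}) = {D:+.2f}  (r={used.get(cls,0.0):.2f}, p={avail[cls]:.2f})")

res = rp.rwm_simulate(track, n_sims=200, seed=11)
r = res["MCP95"]
print(f"RWM null MCP95 CI = ({r.ci[0]:.1f}, {r.ci[1]:.1f}) ha, "
      f"observed = {r.observed_ha:.1f} ha, site fidelity: {r.site_fidelity}")
```

prints

```
href = 144.0 m
MCP95 = 194.64 ha, K95 = 223.07 ha, K75 = 120.35 ha
Jacobs D(lantana) = +0.71  (r=0.70, p=0.28)
Jacobs D(crops_high) = -0.81  (r=0.09, p=0.49)
RWM null MCP95 CI = (869.9, 4653.3) ha, observed = 194.6 ha, site fidelity: True
```

The simulated thicket specialist prefers *L. camara* strongly (D ≈ +0.7),
avoids open cropland (D ≈ −0.8), and uses far less space than its own
unconstrained random-walk null — the signature of site fidelity.

## Command line

`riparia run-all --config config.json --seed 3` runs every stage
(simulate, triangulate, homerange, preference, movement, fidelity, indices,
suitability) and writes CSV/GeoJSON/TIFF artifacts plus a `manifest.json`
to the configured output directory. Individual subcommands run single
stages; exit codes are 0 (success), 2 (validation error), 3 (stage
failure).

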