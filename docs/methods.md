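# Methods

This note documents the models implemented in `riparia`, the defaults and
why they were chosen, what the synthetic generator does and does not
emulate, and the numerical decisions that matter.

## Telemetry

A fix is the intersection of the two *forward* bearing rays (azimuths in
degrees clockwise from grid north). Near-parallel pairs
(|sin Δaz| < 10⁻⁶) and intersections behind either observer
(back-bearings) are rejected rather than extrapolated. Azimuths are
grid-north; magnetic-declination correction is the caller's duty. The
observer-distance filter is strict: a fix at exactly 1000 m is kept, one
beyond it removed. Turning angles are wrapped to (−180°, 180°] with
positive = clockwise — the same convention the random-walk resampler uses,
which is the property that actually matters.

## Home ranges

**MCP** retains the fixes whose centroid distance is at most the
empirical retention quantile (linear interpolation; points exactly at the
threshold kept) and reports the convex-hull area in hectares. Three or
more non-collinear fixes are required; degenerate geometry raises.

**Kernel UD.** The bandwidth is the bivariate normal-reference ("ad hoc")
form `h = sqrt((var x + var y)/2) · n^(−1/6)` with the n−1 variance — the
standard reading of that phrase in the telemetry literature. The UD is an
exact sum of isotropic Gaussians evaluated separably on a square grid
(default 5 m cells, matching the imagery resolution) covering the fixes
plus a 3h margin (truncation < 1% of mass), then renormalized to integrate
to one. Isopleths accumulate cells in descending density order, ties
broken by cell index, with a 10⁻¹² relative slack so exact-tie
accumulations (a uniform UD) do not spill one cell; area is cell count ×
cell area (the raster definition is canonical; a polygonized boundary is
available for overlay work). An area-accumulation curve (estimate on the
first k days, k = 2..D) flags saturation when the last day adds < 5% of
the final area.

## Habitat preference and movement

Jacobs selectivity `D = (r − p)/(r + p − 2rp)` uses r from intersecting
the K75 core area with the land-cover map and p from the full mapped study
area (a river-buffer restriction is available). Boundary cases are
resolved algebraically (r = 1 → +1, r = 0 → −1, r = p → 0; the 0/0
corners are NaN) so the analytic limits hold exactly in floating point.
Cohort preference per habitat uses the exact two-sided sign test at
success probability ½, dropping exact zeros (the standard convention; the
source analysis is silent on zeros).

Movement samples are step length × 10/Δt (m·10 min⁻¹) for steps with
Δt ≤ 10 min — longer gaps are excluded rather than rescaled to keep the
unit exact — attributed to the habitat polygon containing the start fix;
classes with ≤ 50 samples are flagged. Between-species differences in
home-range size use a classical one-way ANOVA; `transform="auto"` applies
log(x+1) only when Shapiro–Wilk rejects residual normality at α = 0.05.
The richer mixed-effects structure (per-habitat variances, backward AIC
selection) is deliberately not re-implemented: the module emits the tidy
long table (bird, habitat, response) for standard statistics packages.

## Random-walk null model

For each bird, 1000 bootstrap simulations draw step lengths and turning
angles *independently, with replacement* from the observed sets (the two
sets are resampled separately; joint pair-resampling and permutation modes
are flags), rebuild the path from the observed start point and initial
heading, and record MCP95 and K75 areas. The CI is the empirical 2.5/97.5
percentile interval (linear interpolation); site fidelity is declared when
the observed area lies below the CI. The null kernel runs on a 20 m grid:
the null needs area *ranks*, not cartography, and the coarser grid keeps
1000 simulations per bird cheap. Under its own null (an unconstrained
correlated random walk) the flag fires at the nominal ~2.5% rate — the
suite checks this on 200 replicate datasets.

## Remote sensing

TOA reflectance is `radiance · scale · π · d² / (esun · cos θz)` per band,
clipped to [0, 1]; the coefficients are configuration (they come from the
imagery product metadata), never built-in constants, and the synthetic
generator produces reflectance directly so no fake coefficients circulate.
The seven vegetation indices follow the standard red-edge formulary:
NDVI, GNDVI, NDRE, RENDVI ((RE−R)/(RE+R)), REGNDVI ((RE−G)/(RE+G)),
GCM (NIR/G − 1), GRM (NIR/RE − 1). Any zero denominator or nodata operand
propagates to nodata — no fabricated index values under clouds. Distance
rasters are exact Euclidean cell-centre-to-geometry distances (zero inside
target polygons), computed vectorized against the river line, the mixed
thicket polygons, or the settlement points.

## Suitability models

The core model is the Gibbs density `q(x) ∝ exp(λ·f(x))` over background
cells — the maximum-entropy formulation of presence-background modelling —
with linear, quadratic and pairwise-product features of
background-standardized predictors. Fitting minimizes the regularized
negative presence log-likelihood with an L1 penalty
`reg · sd_j(f) / √n_pres` per feature via an a−b coefficient split under
L-BFGS-B (capped at |λ| ≤ 50 against separation). Raw output sums to one
over the background; the logistic output is `c·r/(1 + c·r)` with
`c = exp(H)`, H the raw distribution's entropy (default prevalence 0.5).
Percent contribution attributes |λ_j·(mean_presence f_j − mean_model f_j)|
to each predictor (product features split half-half), normalized to 100 —
a penalized-gain bookkeeping in the spirit of the classical tool's
"percent contribution", whose exact internals are not public.

The chained design: (1) a pre-model with distance-to-river as the single
predictor, background restricted to the 100% MCP of the pooled fixes,
binarized at the 10-percentile training-omission threshold (the largest t
retaining ≥ 90% of training-presence predictions), becomes the spatial
mask; (2) a *L. camara* sub-model fits random points inside mapped
lantana polygons against the study-area background on the seven indices,
and its logistic probabilities become a predictor; (3) per-species models
inside the mask use the indices, the lantana probability and the
distances to mixed thicket and settlements, with presence cells
deduplicated (one per grid cell) and split 70/30 per replicate
(Bernoulli; a replicate with < 4 test presences is redrawn and logged)
for 10 seeded replicates. Reported: per-replicate training/test AUC
(rank-based, ties 0.5), the mean logistic surface (NaN outside the mask),
the mean threshold, and averaged contributions. Background samples are
capped at 10⁴ cells (seeded subsample). The defaults reg = 1.0 and 10
replicates mirror conventional tool defaults.

## Synthetic data

The generator defines the study conditions; it is not a tuning dial.

* **Landscape** — Voronoi-seeded patches (default 400 on a 2 × 2 km,
  10 m grid) relabelled by distance-to-river priority: thicket classes
  claim the river-nearest patches in proportion to their remaining area
  quotas, crops_low and settlements scatter over the rest, crops_high is
  the matrix. The `mosaic` parameter (default 0.35) jitters the priority
  distance with an exponential term (scale = mosaic · buffer/2), so
  agricultural plots interleave with thicket inside the corridor — the
  fine-grained river mosaic of the study system — while thicket stays
  essentially inside the 400 m buffer. A patch is assigned only where it
  would overshoot its class quota by less than half its own size, keeping
  realized fractions within a few percent of targets. The default class
  mix follows the mapped composition of the study valley (lantana 0.283,
  mixed 0.065, indigenous 0.018, crops_low 0.094, settlement 0.043,
  remainder crops_high).
* **Movement** — a correlated random walk: gamma step lengths (CV 0.6)
  with the mean of the habitat at the current position, von Mises turns
  (κ = 1), optional blending toward the nearest river point. Default
  per-habitat means are the reported movement speeds (lantana 143.9,
  crops_low 402.8, crops_high 315.1, mixed 299.8 m·10 min⁻¹; the two
  unreported classes borrow their structural analogue). With
  `habitat_preference` set, each step draws several candidate headings
  and picks one weighted by the destination habitat — a
  resource-selection walk. This exists because habitat-dependent *speed*
  alone concentrates fix density but not the deduplicated presence cells
  a suitability model trains on; genuine selection requires a choice
  term. Boundary handling mirrors the out-of-extent heading component and
  re-applies the full step length, so recovered step-length distributions
  are unbiased (folding the endpoint would shorten boundary steps).
* **Spectra** — each cell draws Normal(class mean, sd 0.02) per band,
  truncated to [0, 1]; lantana carries a distinct green/red-edge
  signature so the spectral sub-model has signal to find.
* **Bearings** — true observer-to-bird azimuths plus Gaussian noise,
  wrapped to [0, 360); at zero noise, triangulation inverts the generator
  exactly (checked to 10⁻⁶ m).

All randomness in a generator flows through one seeded NumPy generator:
equal seeds give bit-identical landscapes, tracks, bearings and rasters.

**The bundled suitability scenario** (`sdm_scenario`) uses the
*river-buffer* composition (thicket ≈ 12% of the corridor landscape, as
in the 400 m buffer assessments) rather than the ~30% of the small
detailed-mapping area, four thicket specialists with strong lantana
selection and mild river attraction, and 400 fixes each. Under these
conditions the chained model reaches a replicate-averaged test AUC around
0.75 with the lantana probability among the top contributors.

### What the generator does not emulate

No breeding, flocking or territorial dynamics; no temporal autocorrelation
in habitat choice beyond the CRW heading; no observer availability bias,
signal bounce or variable bearing error; no atmospheric or phenological
structure in the spectra (class means are stationary); no mixed-pixel
effects at polygon edges beyond grid discretization. Passing tests
therefore demonstrate that the estimators and models recover known planted
structure under clean sampling — not that they are robust to every
field-data pathology.

## Numerical choices and degenerate inputs

Quantiles use linear interpolation throughout (MCP retention, RWM CI).
Collinear or coincident fixes raise degenerate-geometry errors (MCP,
href). Kernel grids that fail to cover the fixes + 3h margin raise.
`nan` marks undefined Jacobs corners; the sign test refuses all-zero
input; the ANOVA refuses groups with zero within-variance. Maxent
separation is capped with a flag rather than diverging. Problem sizes in
the test suite (2 km landscapes, 10–20 m analysis grids, 200-simulation
nulls, 4 × 10³-cell backgrounds) are chosen so the full suite and the
acceptance script each run in well under a minute of the pipeline's
full-scale equivalents while leaving every statistical conclusion
unchanged at their sample sizes.

## Known limitations

The mask chain fixes the training domain before the species models see
habitat predictors, so a species whose range extends beyond the pooled
MCP is clipped. Contribution shares are penalized-gain attributions, not
permutation importances, and should be read as rankings. The RWM null
ignores habitat (by design — it asks about space use, not selection);
habitat-aware nulls are out of scope. GeoJSON/TIFF I/O records the grid
and a CRS *name* but performs no reprojection; inputs must already be
planar metres.
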