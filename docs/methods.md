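# Methods

This note documents the models and procedures `skygreen` implements, the
defaults and why, what the synthetic data emulate (and do not), and the
numerical conventions a maintainer needs to know.

## Sky-map projection and green visibility

A segmented street-view panorama arrives as an equirectangular label raster:
width `W` columns mapping linearly to azimuth `[0°, 360°)`, height `H = W/2`
rows mapping linearly to elevation from +90° (top row, zenith) to −90°.
Only the sky half (elevation ≥ 0°) enters the analysis.  It is re-rendered
as a hemispheric *sky map*: a square raster containing a disc whose centre
is the zenith and whose rim is the horizon, the format in which
hemispherical ("fisheye") canopy photographs are conventionally analysed.

The disc uses an orthographic mapping in elevation: a sky direction at
elevation φ lands at polar radius `r = R·cos φ`, with `R = W/2π` the sky
chart radius.  The projection is computed inversely: for each output pixel
centre at `(r, θ)` we recover `φ = arccos(r/R)` and azimuth `θ`, and sample
the source raster at the nearest pixel.  Nearest-neighbour sampling is a
requirement, not a convenience — labels are categorical and any
interpolation would manufacture classes.  The pixel at `r = 0` has undefined
azimuth; it is assigned `θ = 0` (any value gives the same sample row, since
`φ = 90°` there).

A second dialect, `literal_formula`, applies the published relation
`Y = (R/r)·√(R² − r²)` verbatim, treating `Y` as source-pixel rows above the
horizon and clipping into the sky half.  Under `r = R·cos φ` that `Y` equals
`R·tan φ`, which diverges at the zenith and cannot index a finite raster;
the dialect exists so the printed construction can be reproduced and
compared, and it is not the default.  Which reading the method's original
source intended cannot be settled from the construction alone, so both are
provided rather than guessed between.

Green visibility is `100 ×` (vegetation pixels / all in-disc pixels), with
the denominator the whole hemisphere above the horizon — sky, buildings and
all — not just "visible sky".  Elevation bands stratify the same counts:
band *b* covers `[edge_b, edge_{b+1})`, with the top band closed at 90°, so
every pixel belongs to exactly one band.  The defaults are the quartile
edges (0, 22.5, 45, 67.5, 90)°.  Under the orthographic mapping, the exact
disc-area share of a band is `cos²(lo) − cos²(hi)`; the four default bands
occupy (0.1464, 0.3536, 0.3536, 0.1464) of the disc, and this closed form
doubles as the normaliser of the analytic scene oracle below.

A band with zero raster pixels (possible only for extremely narrow bands at
coarse resolutions) raises a resolution error rather than silently
reporting zero.

**Default map resolution 1024 px.**  At 1024 px the raster band
percentages of random rectangular-patch scenes deviate from the analytic
values by < 1 percentage point (the discretisation error of a quantised
annulus boundary), and a projection takes ~10 ms once the inverse mapping
for a panorama shape is cached.  The cache (`lru_cache` on panorama shape ×
geometry × band spec) makes batch projection a single fancy-indexing pass
per mask.

**Analytic oracle.**  For scenes made of rectangular azimuth × elevation
vegetation patches, band visibility has a closed form: sweep elevation
slabs between consecutive breakpoints, take the azimuth-union length within
each slab (patches may overlap; the union is exact), and weight by the slab
measure `cos²(a) − cos²(b)`.  The oracle shares no code path with the
raster projection and is the reference for the convergence tests.

## Panorama assignment and seasonality

Each road sample site searches a metadata table for candidate panoramas
within 10 m (projected metres; at neighbourhood scale the difference from
geodesic distance is sub-centimetre) and an acquisition-year window
(default 2013–2015).  Candidates from the greener months April–September
are preferred over any off-season candidate regardless of distance; within
the preferred stratum the nearest wins, then the latest year, then the
lexicographically smallest panorama id.  The last two tie-breaks are this
package's choices — the priority of greener months and the 10-m radius are
the method's substance, the deterministic tie-break is auditability.
Seasons are meteorological (Mar–May spring, …, Dec–Feb winter), and season
percentages are reported to two decimals over resolved sites only.

## Road sampling, network buffers, neighbourhood variables

Roads are polylines in one projected metric CRS; the package is
projection-agnostic and never reprojects.  Motorway-class edges are excluded
from sampling and routing.  Sample sites are placed at offsets 0, 50, 100, …
metres along each edge (never at the far endpoint), and offset-0 points that
coincide with an already-emitted node within 0.01 m are dropped, so a chain
of edges yields evenly spaced, non-duplicated sites.  The resulting count
lies in `[Σ ceil(len/interval) − n_nodes, Σ ceil(len/interval)]`.

A participant's neighbourhood is the set of road locations within 1000 m
*along the network* of their residence.  The residence snaps to the nearest
point of a non-excluded edge (snap tolerance 500 m; exceeding it is an
error, not a silent exclusion, to keep cohort bookkeeping explicit).
Dijkstra runs over the edge graph seeded with the two along-edge distances
from the snapped origin, and each edge's reachable portion is reconstructed
from its endpoint distances — including interior islands on the origin edge
itself — splitting partial edges exactly at the frontier.  The buffer is
therefore a set of per-edge offset intervals; site membership is an exact
interval test, not a geometric proximity test.

Exposure is the unweighted arithmetic mean of each visibility index over
in-buffer sites that resolved an image, and a participant is analysable only
with ≥ 20 such sites (exclusion is a flag, never an exception).  Density and
park counting need an areal region, but a reachable edge set has zero area;
the package dilates it into a corridor polygon of configurable half-width
(default 50 m, roughly half a block) and uses that region consistently for
both.  Population density is areal-weighted: each grid cell contributes its
population times the fraction of the cell inside the region, and the total
is divided by the region's area; a uniform-density grid therefore returns
exactly that density for any region shape.  Parks are counted
boundary-inclusive.

## Outcome scoring and association models

Weekly leisure-walking minutes are reconstructed from two questionnaire
items as `duration(h) × 60 × frequency(/day) × 7`, with duration weights
{0.25, 0.75, 1.5, 2.5, 3.5, 4.0} hours and frequency weights
{0, 0.5/30, 2/30, 1.5/7, 3.5/7 = 0.5, 1} per day.  Unknown category labels
raise; there is no silent default.  Every achievable score is 0 or lies in
[1.75, 1680] min/week.

Each of the five indices (overall + four bands) is fitted **separately** —
never jointly — as the single exposure in a linear mixed model of walking
minutes with a random intercept at the school-district level.  Model A
adjusts for age group (6 levels, reference 20s) and gender; Model B adds
marital status (3-level coding), education (5 levels), family size,
working status, alcohol consumption (4 levels), population density
(entered continuously, scaled to thousands per km² for conditioning) and
park count.  Fits use maximum likelihood, not REML, so AIC is comparable
across fixed-effect specifications; the AIC counts fixed effects plus the
two variance parameters.  The index coefficient is reported with a Wald 95%
CI in min/week per index point.  A boundary fit (random-intercept variance
at zero) is flagged, not discarded.  If a configured categorical reference
level is absent from the sample (possible in small cohorts), the most
frequent observed level becomes the reference.

Complete-case analysis: rows missing any model variable are dropped, with
per-variable removal counts returned; an empty result is an error.

## Synthetic data: what it emulates

`synthgen` generates the three input families with known truth:

* **Scenes** are unions of rectangular azimuth × elevation vegetation
  patches rasterised onto the panorama grid; their visibility truth comes
  from the analytic oracle.  They emulate the *geometry* of street trees in
  a segmentation mask — not segmentation noise, occlusion layering, or
  photographic artefacts.  Passing tests show the projection arithmetic is
  right; they say nothing about upstream segmentation quality.
* **Towns** are rectangular road grids with seeded park points and a 250-m
  population grid (log-normal densities).  They exercise routing, buffers
  and areal interpolation, not realistic street topology.
* **Cohorts** draw covariates from plausible urban-cohort frequencies and
  generate latent weekly minutes as
  `intercept + Σ β·index + covariate effects + district intercept + noise`,
  floored at zero.  Defaults are the recovery-study conditions: true overall
  slope 3.0 min/week per point, district sd 10, residual sd 20, n = 2000
  over 20 districts; the intercept (105) puts the mean near typical
  self-reported leisure-walking levels (~100–150 min/week).  The latent
  value is then snapped to the nearest achievable
  (duration × frequency) grid value and emitted as the two categories, so
  the outcome scorer round-trips bit-exactly.  Per-participant index
  draws (`synthetic_exposures`) follow the marginal means/SDs typical of
  street-level greenery in a mid-size city (overall ≈ 7% ± 3.5), with a
  shared factor inducing the positive band correlation real scenes produce.

**The measurement layer is deliberately coarse.**  Snapping onto the
questionnaire grid is a step function whose plateaus (up to ~50 min/week
wide in the 130–210 range) distort a fitted slope systematically, exactly
as categorical instruments do in real cohorts.  The estimator-calibration
suites (parameter recovery, CI coverage, type-I rate) therefore evaluate
`fit_association` against the continuous latent outcome — the generative
model the estimator assumes — where it is unbiased and nominally calibrated.
The measurement layer is validated separately: by the exact round-trip
identity, and by the end-to-end demo, whose per-index truths are defined as
the least-squares projection of the *measured* outcome's conditional mean
(Monte-Carlo over the generative noise, marginally over district effects —
the expectation under which the mixed-model slope is unbiased) onto each
single-index design.  Under those definitions the demo's five CIs cover
their truths; individual nominal-rate misses remain possible at other
seeds, as they should.

## The demonstration pipeline

`skygreen demo` chains every stage on a 6×6 grid town (250 m blocks,
275 sample sites), a smooth spatial greenness field driving per-site tree
scenes (so exposures vary between neighbourhoods), a 5% unresolved-imagery
rate, 600 participants in 9 block districts, 1000-m buffers, and Model A/B
fits.  One run takes ~20 s on one CPU and is bit-reproducible under a fixed
seed: all randomness flows through explicit `numpy` generators seeded from
the single demo seed, and no global random state is touched.  Panorama
width 832 px and the 1024-px sky map keep the projection error well inside
the oracle tolerance.

## Known limitations

* Segmentation is an input boundary: no inference, and no label-noise model.
* The network is undirected and unimodal — no one-way restrictions, grade
  separation, or crossing penalties; parallel edges between the same node
  pair are collapsed to the shorter.
* The corridor half-width for density/parks is a modelling choice (50 m
  default); a 1-D neighbourhood has no canonical area.
* The outcome's zero spike is produced by the "almost none" frequency
  category, not by a censoring model; Tobit-style alternatives are out of
  scope.
* Reported significance is unadjusted for testing five correlated indices.
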