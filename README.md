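# skygreen

Elevation-stratified streetscape green visibility from street-view panorama
segmentations, road-network neighbourhood exposure, and its association with
leisure walking.

## The problem

Street greenery seen from a pedestrian's eye level is repeatedly linked to
recreational walking, but "percentage of green pixels in a photo" ignores
*where* in the visual field the greenery sits: a lawn at one's feet and a tall
tree canopy overhead contribute very differently to shade, comfort and
aesthetics. `skygreen` implements an exposure pipeline for
built-environment epidemiology that stratifies street greenery by elevation
angle in the pedestrian's virtual hemisphere, aggregates it over realistic
road-network neighbourhoods, and relates it to self-reported walking time
with multilevel models.

The pipeline has four stages, each usable on its own:

1. **Sky-map projection** (`skygreen.skyproj`).  A street-view panorama in
   equirectangular projection (360° azimuth × 180° elevation, `H = W/2`)
   is segmented into per-pixel class labels upstream (segmentation is an
   input, not part of this package).  The sky half is re-rendered as a
   hemispheric disc — centre = zenith, rim = horizon — with the orthographic
   mapping `r = R·cos φ`, `R = W/2π`.  Green visibility is the percentage of
   disc pixels whose label is a vegetation class, computed overall and
   within four elevation bands (0°–22.5°, 22.5°–45°, 45°–67.5°, 67.5°–90°).
   Under the orthographic mapping the band areas are exactly
   `cos²(lo) − cos²(hi)`: (0.1464, 0.3536, 0.3536, 0.1464) of the disc.
2. **Panorama assignment** (`skygreen.imagery`).  Each road sample site
   picks the closest panorama within 10 m, preferring images from the
   greener months (April–September) regardless of distance.
3. **Neighbourhood exposure** (`skygreen.geoexposure`).  Sample sites are
   placed every 50 m along non-motorway roads; a participant's
   neighbourhood is everything within 1000 m *along the network* of their
   residence; exposure is the unweighted mean of site-level visibility over
   in-buffer sites, kept only if at least 20 sites resolved an image.
   Population density (areal-weighted from a population grid) and park
   counts are computed on a corridor polygon around the reachable streets.
4. **Outcome and models** (`skygreen.cohort`).  Weekly leisure-walking
   minutes are scored from two questionnaire categories as
   `duration(h) × 60 × frequency(/day) × 7`, and each of the five greenery
   indices is fitted separately against it with a linear mixed model
   (random intercept per school district; ML fit, Wald 95% CI):
   Model A adjusts for age group and gender; Model B adds marital status,
   education, family size, working status, alcohol use, population density
   and park count.

Because the cohort, imagery and GIS layers such a study uses are not
redistributable, `skygreen.synthgen` generates all inputs with known ground
truth — scenes of rectangular vegetation patches with closed-form
visibility, a grid-town road network, and cohorts drawn from the generative
linear model with the questionnaire's categorical measurement layer — so
every stage is verifiable end to end.

## Worked example

```sh
$ skygreen demo --seed 7 --out demo_out/
      index model      beta  ci95_lo   ci95_hi         aic  n_used  random_intercept_sd  singular
overall_pct     A  2.669517 1.212855  4.126178 5353.481751     600            12.297937     False
  band1_pct     A  1.641005 0.673028  2.608982 5355.378535     600            12.211977     False
  band2_pct     A  1.856738 0.864051  2.849426 5352.931751     600            12.318858     False
  band3_pct     A  3.922687 1.761305  6.084070 5353.769127     600            12.286191     False
  band4_pct     A 11.616440 5.079690 18.153189 5354.322830     600            12.238480     False
```

The demo builds a 6×6 grid town (250 m blocks), renders a segmentation mask
for each of its 275 road sample sites from a smooth spatial greenness field,
projects each to a 1024-px sky map, assigns panoramas (a few sites are
unresolved, as in real metadata), computes 1000-m network-buffer exposures
for 600 simulated residents, draws their walking outcome from a linear model
with a true overall-greenery slope of **3.0 min/week per percentage point**
plus district random intercepts (sd 10) and residual noise (sd 20), and fits
Model A for each index.  Each `beta` is the fitted slope in minutes per week
per point of that index (the zenith band spans a much narrower range than
the horizon band, so its per-point slope is correspondingly larger); all
five 95% CIs cover the generative marginal truths recorded in
`demo_out/truth_manifest.json`.  The mask PNGs, site and
exposure tables, cohort and fitted results are written alongside.

The library surface mirrors the CLI:

```python
from skygreen import (BandSpec, SkyMapGeometry, build_skymap,
                      green_visibility)
from skygreen.io import read_label_png

mask = read_label_png("pano_labels.png", vegetation_ids={8})
sky = build_skymap(mask, SkyMapGeometry.for_mask(mask, 1024))
rec = green_visibility(sky, site_id="site-001")
rec.overall_pct, rec.band_pct   # e.g. 14.65, (100.0, 0.0, 0.0, 0.0)
```

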