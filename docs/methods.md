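# Methods

This document records the model equations, the synthetic-scene generator,
all parameter values, and the numerical and software-design choices made in
`minescore`.  It is the companion to the worked example in the README.

## 1. Data model

All raster computation happens on a shared `GridSpec`: a planar, north-up
lattice (default 200 × 200 cells at 30 m) with the origin at the top-left
corner and coordinates in metres of an unspecified projected CRS.  A `Grid`
is one band of values on that lattice with an optional nodata value and a
continuous/categorical tag.  Vector inputs (mine features, rivers, lakes,
protection areas) are shapely geometries; mine features additionally carry
three controlled vocabularies: feature class (stope, open_pit,
concentrator_plant, ore_pile, coal_pile, dumping_site, tailings_pond),
mineral (metal / non_metal) and method (open_pit / underground).
Meteorology is a `StationSeries` per station: twelve monthly records of
rainfall, temperature, solar radiation, AQI and wind speed.

Rasterization uses the cell-centre rule (a cell is covered iff its centre
lies on or inside a geometry).  Distances are exact Euclidean point-to-
geometry distances of cell centres.  Min–max normalization maps each layer
onto [0, 1]; a layer whose relative spread is below 1e-12 is treated as
constant and maps to all zeros, so floating-point summation noise in a
physically uniform field is never amplified to full scale.

## 2. Regional eco-environmental status (EI)

The EI score is a weighted sum of five normalized indices:

```
EI = 0.35·biological_abundance + 0.25·vegetation_coverage
   + 0.15·river_density + 0.15·(1 − land_stress)
   + 0.10·(1 − pollution_loading)
```

and is classified into five levels at breaks 0.2 / 0.4 / 0.6 / 0.8
(level 1 "very bad" … level 5 "very good"; a break value belongs to the
upper class).

### 2.1 Biological abundance

Habitat quality weights each cell by its land-use class weight (woodland
0.35, water/wetland 0.28, grassland 0.21, arable 0.11, construction 0.04,
unutilized 0.01) times its habitat-subtype weight within the class (e.g.
woodland 0.60 / shrubbery 0.25 / sparse woodland 0.15).  Biological
abundance is the normalized product of habitat quality and a biological
richness surface.

### 2.2 Vegetation coverage via CASA NPP

Monthly NPP = APAR × ε, where

- APAR = total solar radiation × 0.5 × FPAR;
- FPAR is the mean of an NDVI-anchored and a simple-ratio-anchored linear
  stretch, where SR = (1 + NDVI)/(1 − NDVI) and both stretches map the
  per-land-class 5th/95th percentiles onto [0.001, 0.95] with clamping;
- ε = ε_max × temperature stress × water stress, with ε_max per vegetation
  type: woodland 0.638, shrubbery 0.429, sparse woodland 0.475, all other
  classes 0.542 gC/MJ.  Temperature and water stress are standard CASA
  forms driven by kriged monthly temperature and a rainfall-based moisture
  ratio.

Seasonal NPP is the sum of the season's three months (March-first study
year: spring = MAM, …, winter = DJF); the vegetation-coverage index is the
normalized seasonal NPP.  Per-class percentile anchors fall back to global
anchors when a class has too few cells, and a fully degenerate NDVI field
raises rather than producing arbitrary anchors.

### 2.3 River density

```
raw = 84.3704·river_length + 591.7909·lake_area + 86.387·water_resources
```

evaluated per cell as circular moving-window means (radius 1000 m) of river
length per cell and lake area per cell, plus a scene-level water-resources
scalar; the result is min–max normalized.  River length per cell is the
exact length of the river network intersected with each cell's square.

### 2.4 Land stress

Erosion classes (severe / other / none, derived from slope and erodible
soils — cinnamon and loess) carry weights 0.4 / 0.2 / 0.0.  The raw index
is 236.0436 × the circular window mean (radius 1000 m) of the weight field,
then min–max normalized.

### 2.5 Pollution loading

Normalized kriged AQI.

## 3. Mine-impact factor layers

All four layers are normalized to [0, 1]; larger means worse.

- **Air pollution**: 1 / wind speed within 50 m of open pits and
  concentrator plants, 0 elsewhere; normalized over the support (a
  constant in-support value maps to 1.0, not 0, because presence of the
  source is the signal).
- **Solid waste**: graded presence around ore piles, coal piles and
  dumping sites.
- **Geologic hazard**: graded presence around underground stopes and coal
  piles.
- **Soil pollution**: concentric graded buffers with ring value
  (k − i + 1)/k; non-metal workings and all coal piles use breaks
  30 / 200 / 1000 m, metal-related features use 50 / 100 / 300 / 500 m;
  the two buffer grids combine as an elementwise maximum.

**Region split**: cells within 1000 m of any mine feature form the mining
region; protection areas are forced into the non-mining region.

## 4. Kriging

Station monthlies are interpolated by ordinary kriging with a spherical
variogram (γ(0) = 0 exactly).  Range and sill are fitted to binned
empirical semivariances by bounded least squares; with fewer than four
stations, zero variance, or a failed fit, the fallback is range = half the
maximum station separation and sill = the sample variance.  Each cell uses
its 12 nearest stations; cells sharing the same neighbor set are solved in
one batched linear system.  A singular kriging matrix (e.g. consistent
duplicate stations) falls back to inverse-distance weighting with a
warning; duplicate stations with conflicting values raise.

## 5. Synthetic scene generator

`make_scene(SceneConfig(...))` builds the full study scene from one seed:
a smoothed DEM and slope, a land-use/habitat mosaic drawn from a target
mixture, soil classes, monthly NDVI consistent with land use and season,
rivers and lakes, 8 meteorological stations with a monsoon-concentrated
rainfall year (annual 583 mm, mean 14.5 °C), and 6 mine sites (40 % metal)
whose features carry the controlled vocabularies.  Generator defaults are
the study conditions; they are not tuned per experiment.

`make_samples` draws scored field points: 700 in the non-mining region
(stratified over land use) and 100 in the mining region.  Mining points
are drawn half within 100 m of a mine feature and half anywhere within
the 1000 m mining region, so the small-support factor layers (air, solid
waste, hazard) are represented in the training set.  Each sample's
reference score is the true linear score of its cell's stacked features,
optionally perturbed with Gaussian noise (default sd 0.05) and clipped to
[0, 1] — emulating imperfect field assessments.

## 6. Score models, selection and fusion

Per region, three model families are trained on the 9-layer feature
vector: support-vector regression (`svm`), a CART-style regression tree
(`cart`), and a shallower, leaf-regularized tree variant (`c50`).
Hyperparameters are chosen by seeded repeated cross-validation (3 × 4
folds) over a fixed grid — SVR spans linear and RBF kernels
(C ∈ {0.3…100}, ε ∈ {0.003, 0.05}, γ ∈ {0.01, 0.05}); trees span depth
{6, 10, 14} × min-leaf {1, 3, 8} — with the one-standard-error rule:
among configurations within one standard error of the best mean CV error,
the least flexible one is selected.  This guards against fitting the
reference-score noise in the small mining sample.

25 % of each region's samples are held out before training; the family
with the best held-out five-level agreement is selected per region, and
the two regional predictions (clipped to [0, 1]) are fused into one map.
Reports are per-region × per-land-use agreement tables and Pearson
correlations between the fused map and every input layer (zero-variance
layers give NaN).

With reference-score noise sd 0.05 against a class width of 0.2, even a
perfect model disagrees with the noisy reference labels on roughly 15–20 %
of held-out points; observed agreements must be read against that ceiling.

## 7. Numerical choices

- Circular window means use `scipy.ndimage.convolve` on the value field
  and on the valid-cell indicator, dividing sums by counts — exact
  (edge-correct) window means, not approximations.
- Kriging systems are solved per unique neighbor set in batched
  `numpy.linalg.solve` calls.
- All stochastic steps take explicit integer seeds and use
  `numpy.random.default_rng`; end-to-end runs with equal seeds produce
  byte-identical output files (fixed-order computation, no hash-order or
  thread nondeterminism).
- Rasters are written as single-band TIFFs (float32 continuous, uint8/16
  categorical) with the grid spec and nodata stored as JSON in the
  ImageDescription tag; readers validate the spec against the run's
  reference spec.

## 8. Design choices

- The assessment API follows the statsmodels shape: `EcoAssessment`
  holds data and configuration, `fit(seed)` returns an
  `EcoAssessmentResults` with `summary()`, report tables, and the fused
  map.
- Layers travel in a `FeatureStack` with a provenance hash so fitted
  results can be traced to the exact inputs.
- The scene generator lives in the package so the pipeline is runnable
  and testable offline with no data download.

## 9. Limitations

- The scene is synthetic: spatial structure (field smoothness, mine-site
  geometry, monsoon profile) is plausible but not calibrated to any real
  landscape, so absolute index values are not transferable.
- The CASA sub-model uses simplified stress terms and monthly station
  kriging; with 8 stations the meteorological surfaces are smooth and
  under-represent local variation.
- Reference scores are linear in the stacked layers by construction, so
  model families are compared on noise robustness and spatial
  generalization, not on their ability to discover non-linear structure.
- The mining region holds only 100 samples; selection between families on
  a 25-point holdout is noisy, which is why the repeated-CV +
  one-standard-error rule biases toward regularized models.
- Pearson correlations of map versus single layers are descriptive; they
  are confounded between correlated layers and are reported as a sign and
  structure check, not as effect sizes.
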