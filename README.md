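# minescore

Eco-environmental assessment of mining landscapes: a five-index
eco-environmental status (EI) model with a light-use-efficiency (CASA) net
primary productivity sub-model, four mine-impact factor layers, ordinary
kriging of station meteorology, and per-region machine-learned score maps —
runnable end to end on a fully synthetic study scene.

## The science

Mining regions degrade in ways that a generic regional eco-index misses:
open pits, waste piles and underground stopes create sharp, local impacts
(dust, solid waste, ground deformation, soil contamination) superimposed on
the broad landscape signal of vegetation, water and land use.  `minescore`
models both scales and fuses them:

1. **Regional EI score.**  Five normalized indices are combined as

   `EI = 0.35·biological_abundance + 0.25·vegetation_coverage +
   0.15·river_density + 0.15·(1 − land_stress) + 0.10·(1 − pollution_loading)`

   and classified into five levels (very bad … very good) at breaks
   0.2 / 0.4 / 0.6 / 0.8.  Vegetation coverage comes from a CASA-style NPP
   model (APAR × light-use efficiency, with FPAR blended from NDVI and the
   simple ratio, per-land-class ε_max, and temperature/water stress from
   kriged station meteorology).  River density and land stress follow
   area/length-weighted formulas evaluated in a circular moving window.

2. **Mine-impact factors.**  Four normalized factor layers are computed
   from the mapped mine features: air pollution (inverse wind speed near
   open pits and concentrator plants), solid waste occupation (ore/coal
   piles and dumping sites), geologic hazard (underground stopes and coal
   piles), and soil pollution (graded concentric buffers around workings,
   with metal-related features carrying wider rings).

3. **Region split and score models.**  Cells within 1000 m of a mine
   feature form the *mining* region; the rest is *non-mining*.  In each
   region, support-vector regression and two decision-tree variants are
   trained on scored sample points against the nine stacked layers; the
   best model per region (held-out five-level agreement) predicts its
   region's score, and the two predictions are fused into one seasonal map.

4. **Reports.**  Per-region and per-land-use five-level agreement tables,
   and Pearson correlations between the fused map and every input layer.

Everything runs on a synthetic scene generator (default 200×200 cells at
30 m; land-use mosaic, NDVI, rivers/lakes, eight meteorological stations,
six mine sites) so the whole pipeline is reproducible without any data
download.

## Worked example

```python
from minescore import SceneConfig, make_scene, make_samples, EcoAssessment
from minescore.assessment import compute_layers

scene = make_scene(SceneConfig(seed=0))          # synthetic study area
layers = compute_layers(scene)                   # nine-layer feature stack
samples = make_samples(scene, seed=0)            # 700 + 100 scored points
res = EcoAssessment(layers.stack, samples, layers.mask,
                    scene.land_use).fit(seed=0)
print(res.summary())
```

This prints (exact output of the above, ~40 s on one CPU):

```text
Eco-environment assessment results
==================================================
stack hash    : be8fbc22fbfd5467…
fit seed      : 0

 non_mining: SVM  accuracy 99.43 %  rmse 0.0013  (n_val=175)
             c50    96.00 %  rmse 0.0609
             cart   94.86 %  rmse 0.0196
             svm    99.43 %  rmse 0.0013
     mining: SVM  accuracy 76.00 %  rmse 0.0529  (n_val=25)
             c50    60.00 %  rmse 0.0981
             cart   64.00 %  rmse 0.0875
             svm    76.00 %  rmse 0.0529

Pearson r (map vs layer):
  biological_abundance   +0.844
  vegetation_coverage    +0.734
  river_density          +0.425
  land_stress            -0.518
  pollution_loading      +0.080
  air_pollution          -0.189
  solid_waste            -0.108
  geologic_hazard        -0.088
  soil_pollution         -0.363

Class shares:
  very bad     9.2 %
  bad         50.2 %
  moderate    34.2 %
  good         6.4 %
  very good    0.0 %
```

The fused map (`res.map.score`, `res.map.classes`) is a `Grid` ready for
`minescore.io.write_raster`.  The signs of the Pearson row are the sanity
check: the map rises with vegetation and biological abundance and falls
with land stress and every mine factor.

### Command line

```sh
minescore generate-scene --seed 0 --out scene_dir
minescore run --seed 0 --season all --out run_dir
minescore report --run run_dir
```

`run` writes `{season}_score.tif`, `{season}_class.tif`, `accuracy.csv`,
`pearson.csv` and `provenance.json`.

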