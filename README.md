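# standagb

Aboveground-biomass (AGB) estimation for sparse, young plantation stands by
fusing drone LiDAR point clouds with Sentinel-2-style multispectral imagery.

Young afforestation stands — single-species plantations of poplar, Mongolian
Scots pine and Chinese red pine with low canopy cover — are poorly served by
satellite-only biomass models, and field campaigns cannot supply enough
training plots at regional scale. This package implements the workflow that
substitutes LiDAR-derived samples for field plots, for remote-sensing
scientists and forest-inventory analysts:

1. **Individual-tree segmentation** of the height-normalized point cloud by
   seeded, top-down region growing: the highest unprocessed return founds a
   crown; lower returns join the nearest crown when their horizontal
   distance is below a spacing threshold (the field mean crown diameter).
2. **Height–diameter growth models**. Four two-parameter curves are fitted
   per species to field (H, D) pairs and compared:

   | form | H(D) |
   |---|---|
   | linear | H = a + b·D |
   | power | H = 1.3 + a·D^b |
   | logarithmic | H = a + b·ln D |
   | Bates (hyperbolic) | H = a·D/(b + D) |

   scored by SSE = Σ(P−O)², RMSE = √(SSE/n), R² = 1 − SSE/Σ(O−Q)² and
   AIC = n·ln(SSE/n) + 2k; the AIC-best form is inverted to predict DBH
   from LiDAR tree heights.
3. **Allometric per-tree biomass** Ma = c·D^p·H^q (kg), with species-specific
   coefficient branches for D < 5 cm and D ≥ 5 cm stems, following the
   Chinese national standard GB/T 43648-2024.
4. **Grid samples**: per-tree biomass is summed over 30-m cells,
   AGB = Σ Ma_i / S in g/m², with cells on stand edges, near mapped
   roads/buildings, or mixing species removed.
5. **26-variable predictor stack** at 30 m: bands B2–B8, B11, B12; NDVI,
   RENDVI, NDWI, EVI, RVI, DVI, VDVI, SAVI, MSAVI, NBR, NDMI; tasseled-cap
   brightness/greenness/wetness as fixed 13-band linear combinations; DEM,
   slope and aspect.
6. **Gradient-boosted regression trees** (GBDT): one fixed random 80/20
   split, grid search over learning rate {0.005, 0.010, 0.050, 0.001} and
   tree count 100–800 scored by held-out R², plus an impurity-based
   variable-importance ranking and wall-to-wall raster prediction.

A synthetic-scene generator with exact ground truth (tree lists on known
growth curves, LiDAR-like clouds, reflectance encoding true biomass) makes
every stage testable end to end; see `docs/methods.md` for the model and its
assumptions.

## Worked example

The numbered scripts under `analysis/` run one desk-scale experiment
(≈7.3 ha, 4 stands, 350 stems/ha, 6 pts/m²) step by step into a shared
working directory:

```sh
cd analysis
python 01_simulate_scene.py            --workdir ../results/experiment --seed 11
python 02_ground_filter_normalize.py   --workdir ../results/experiment
python 03_segment_trees.py             --workdir ../results/experiment
python 04_fit_growth_models.py         --workdir ../results/experiment
python 05_build_agb_samples.py         --workdir ../results/experiment
python 06_extract_features.py          --workdir ../results/experiment
python 07_train_estimator.py           --workdir ../results/experiment
python 08_predict_and_evaluate.py      --workdir ../results/experiment
```

which prints, stage by stage:

```
scene: 2552 trees in 4 stands, 450456 LiDAR returns at 6 pts/m^2
334142 ground returns (recall vs truth 1.000), 5777 flagged as noise, 1 outside-hull fallbacks
2552 trees segmented at spacing threshold 2.00 m (min height 2.0 m)
poplar: bates (a=22.966, b=9.765, R2=0.951)
mongolian_scots_pine: power (a=1.257, b=0.682, R2=0.930)
chinese_red_pine: linear (a=1.526, b=0.598, R2=0.951)
64 clean samples, 17 edge-flagged cells removed, 0 trees outside the inversion domain, 0 trees outside all stands
26 layers assembled; missing-value counts: none
best pair: ntree=800 shrinkage=0.01
train   R2=1.000 RMSE=0 g/m^2
heldout R2=0.998 RMSE=29 g/m^2
top-5 importance: B11 (0.12), B2 (0.07), B6 (0.07), TCW (0.06), NDWI (0.06)
samples vs truth: R2=1.000 RMSE=5 g/m^2 over 64 cells
cells with >=3 trees: median rel err 0.025, max 0.056
prediction vs truth: R2=0.999 RMSE=14 g/m^2
```

Reading the output: every one of the 2552 simulated trees is found again by
segmentation; the AIC-selected growth-model form per species matches the
form that generated the data, with parameters close to truth; the 30-m
sample cells reproduce the true cell biomass to a few percent; and the
boosted-tree model explains ≈99.8% of held-out sample variance with the
biomass-signal-bearing spectral variables leading the importance ranking.

The same pipeline is available as a CLI (`standagb <stage> --workdir …
--seed …`, or `standagb demo` for all stages at once), configured either by
flags or a YAML file.

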