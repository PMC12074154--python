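# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `standagb`. Units throughout: geometry in meters (a single
local projected CRS), DBH in centimeters, per-tree biomass Ma in kilograms,
per-area AGB in g/m².

## Ground filtering and height normalization

Classification is a simplified progressive TIN densification. Seeds are the
lowest return of every 5-m grid cell (`grid_m`, default 5 m — coarse enough
that at least one seed per cell is a true ground hit in sparse stands, fine
enough to track gentle terrain). The seed set is triangulated (Delaunay) and
candidates within `z_tol` (default 0.3 m) of the linearly interpolated
surface are accepted; the loop repeats to `max_iter` (default 10) or
convergence. Candidates outside the triangulation hull are compared against
the nearest ground return. The procedure depends only on coordinates, so a
second application reproduces the labels exactly. Before classification, a
statistical outlier filter (mean distance to k=8 neighbors, cutoff mean +
3·sd) relabels isolated returns as noise without dropping them, so point
counts are conserved through the whole chain.

Normalization subtracts the TIN-interpolated ground elevation from every
return; points outside the hull again fall back to the nearest ground
return, and the count of such extrapolations is reported.

## Individual-tree segmentation

Returns at or above `min_height` (default 2 m) are processed in strictly
descending height. The first (highest) point founds tree 1 and is its apex;
each subsequent point joins the segment owning its nearest already-assigned
point when that horizontal distance is under the spacing threshold, and
founds a new tree otherwise. Determinism is pinned by two tie-breaks:
processing order falls back to (x, y) at equal heights, and a point
equidistant to two segments joins the lower tree id. Distance to a segment
is distance to its nearest member (area growth), not to the apex, tracked in
a spatial hash with cell edge equal to the threshold so each query touches
only a 3×3 neighborhood.

The spacing threshold defaults to the field mean crown diameter of the
stand, the quantity a survey crew would provide. Detection is only well
posed when apexes are separated by at least about twice the threshold;
under that condition the test suite requires recall and precision ≥ 0.95.
Crown area is the 2-D convex hull of the member points (zero and flagged
for degenerate segments), crown diameter the equal-area circle diameter.
Crown volume is deliberately not computed (nothing downstream consumes it).

## Height–diameter models and DBH inversion

The four forms (linear, power anchored at breast height 1.3 m, logarithmic,
Bates hyperbola) are fitted by least squares — closed form for the two
linear-in-parameters forms, `scipy.optimize.least_squares` capped at 500
evaluations for power (start a=1, b=0.5) and Bates (start a = 1.1·max H,
b = median D; both inside the admissible region for forest data).

Fit metrics: SSE, RMSE = √(SSE/n), R² = 1 − SSE/TSS, and the Gaussian-MLE
AIC = n·ln(SSE/n) + 2k with the additive constant dropped — shared by all
candidates, so rankings are unaffected (a property the tests pin). All
forms have k = 2, so at fixed n the AIC order equals the SSE order; AIC is
still computed and reported for fidelity. Selection takes the minimal AIC,
ties broken by higher R², then by the canonical form order. R² is reported
exactly as defined, without clamping to any interval.

Inversion maps LiDAR height to DBH through the selected curve's algebraic
inverse. Out-of-domain heights cannot give a physical diameter and are
flagged (NaN) and counted rather than extrapolated: power requires
H > 1.3 m; Bates heights within 0.5% below the asymptote a are clamped to
the capped inverse, heights at or above a are flagged; any non-positive
inverted diameter is flagged. Flagged trees are excluded from the sample
set, with the count reported.

Model-selection consistency is exercised with all four truth curves
anchored to the same stand envelope — (D, H) = (2 cm, 4 m) and
(30 cm, 12 m), the smallest and largest tree of the simulated stands over a
standard 2–30 cm inventory caliper range — so the candidate curves describe
identical stands and differ only in shape (`height_dbh.anchored_params`).
At the study conditions (n = 200 pairs, 0.5 m height noise) each generating
form wins AIC selection in ≥ 99 of 100 replicates. The logarithmic/power
pair is the least identifiable: for small exponents the power form nearly
nests a shifted logarithm, so narrower diameter ranges degrade its
selection rate — a genuine statistical limit, not an implementation one.

## Allometry and grid samples

Per-tree biomass is Ma = c·D^p·H^q with species- and size-class-specific
coefficients (GB/T 43648-2024) for poplar, Mongolian Scots pine and Chinese
red pine; the branch boundary D = 5 cm belongs to the large-stem branch,
and the two branches are used exactly as published, without smoothing the
small discontinuity at the boundary. The published per-model R² and mean
prediction error are carried as metadata only — their source data are not
available to recompute them.

Samples aggregate trees by 30-m half-open grid cells aligned to the feature
raster: AGB = Σ Ma·1000 / 900 g/m². A cell is edge-flagged (excluded from
the sample set but reported, with its biomass, so totals are conserved)
when it is not fully covered by a single stand polygon, intersects an
exclusion polygon (roads/buildings enter only through this mask), or
contains more than one species. Cells without trees are omitted entirely —
empty ground is not a biomass sample. The conservation identity
Σ cells (AGB·S) = 1000·Σ trees Ma is tested to 1e-6 relative.

## Predictor stack

All layers live on one 30-m grid; finer inputs are nearest-neighbor
resampled (values drawn from source cells, never interpolated). The eleven
vegetation indices follow their standard band formulas; zero-denominator
pixels become missing values and are counted and excluded from training.
The tasseled-cap components are fixed 13-coefficient dot products over
(B1…B12, B8A). The default coefficient vectors are all-positive, including
greenness; published Sentinel-2 conventions carry negative visible-band
greenness coefficients, so `tasseled_cap` accepts replacement vectors for
users who prefer the signed convention — the default is kept as configured
for fidelity with the variable set this pipeline reproduces. Terrain slope
and aspect come from Horn's 3×3 method on the (resampled) DEM; aspect is
reported as the upslope azimuth clockwise from north (a plane rising due
east has aspect 90°) with −1 as the flat-cell sentinel. The stack carries
exactly 26 named layers; assembling with a missing band fails with an error
naming every dependent layer.

## Boosted-tree estimator

`GradientBoostingRegressor` (squared-error loss, depth 3, no subsampling —
depth and subsampling are not dictated by the protocol, so standard
regression defaults are exposed in `GBDTConfig`). One fixed random 80/20
split serves the whole grid search — the protocol specifies a single
train/validation split, not cross-validation — and the split seed is
recorded in the bundle. The grid is learning rate {0.005, 0.010, 0.050,
0.001} × trees 100–800 step 100, scored by held-out R²; ties prefer fewer
trees, then smaller shrinkage. Because boosting without subsampling is
deterministic and incremental, the tree-count axis is scored from one
staged fit per learning rate, which the tests verify is identical to
refitting each size separately. The winning pair is refit and reported
with train and held-out metrics; the winner is data-dependent and no
particular pair is privileged. Importance is the normalized total
squared-error reduction per variable over all splits (summing to 1);
predictions are clipped at zero.

## The synthetic scene generator

The generator emulates the data sources of a sparse-plantation survey and
is the single source of ground truth for the tests:

- **Stands**: the extent is tiled into single-species rectangular stands
  (default 120-m tiles) with a per-stand mean height drawn uniformly from
  the height range (default 4–12 m), giving between-stand biomass contrast.
- **Trees**: apex positions by dart throwing with a scene-wide minimum
  separation (default: the mean crown diameter; the packing feasibility
  check rejects configurations demanding closer spacing). Tree heights are
  uniform within ±15% of the stand mean; DBH is the exact inverse of the
  species' true growth curve (defaults: Bates(22, 9) for poplar,
  power(1.2, 0.7) for Mongolian Scots pine, linear(1.5, 0.6) for Chinese
  red pine), and Ma is exactly the allometric equation — so every
  downstream estimate has an exact target.
- **Point cloud**: ground returns uniform over the extent plus a 2-m survey
  margin (so crowns spilling past the boundary still sit above sampled
  terrain), on a gentle analytic terrain surface; crown returns on conical
  (pines) or paraboloid (poplar) envelopes with crown diameter 0.25·H ±10%
  and crown base max(2, 0.3·H) m, radially concentrated toward the crown
  center, at 3× the pulse density over the crown footprint (triple-echo
  emulation) with the intercepted pulses debited from the ground budget;
  one guaranteed apex return per tree plus a small treetop echo cluster;
  Gaussian vertical noise (default sd 0.03 m). Default pulse density is
  450 pts/m², matching the emulated survey; the desk-scale experiments in
  `analysis/` and the acceptance script run at 6 pts/m² (≈7 ha scenes),
  which the stated tolerances already accommodate.
- **Reflectance**: each of the 13 bands is base + gain·L(A) + N(0, sd) with
  L a logistic in the true cell AGB (midpoint 500 g/m², scale 350 g/m² —
  near-linear over the tens-to-~2000 g/m² envelope the default stands
  produce). NIR and red-edge bands rise with biomass; red, blue and SWIR
  fall; B1/B9/B10 carry no signal. Default noise sd 0.005 (≈1.5% of the
  largest band range). Every predictor derived from a signal band is listed
  in `SIGNAL_FEATURES`; only DEM, slope and aspect are signal-free.
- One `numpy` generator seeded per scene drives every draw, so scenes are
  byte-reproducible.

What the generator does **not** emulate — and therefore what passing tests
do not demonstrate about real data: occlusion and partial canopy
penetration, multi-layer or mixed-species canopies, understory shrubs,
atmospheric and soil-background spectral effects, co-registration error
between LiDAR and imagery, and growth-curve scatter between trees (trees
sit exactly on the species curve; only the simulated field pairs carry
measurement noise). Real-data validation would replace stages 1–2 inputs
with actual surveys.

## Numerical and degenerate-input conventions

Zero-variance observations make R² undefined: it is returned as missing
with a flag, never as a number. SSE = 0 maps to AIC = −∞, which orders
correctly. Empty clouds and clouds with no point above the minimum height
segment to an empty list (not an error); fewer than 3 TIN seeds, fewer than
3 (H, D) pairs, unknown species, non-positive D or H, CRS mismatches and
missing bands are errors that name the offending input. Degenerate crown
hulls (under 3 points or collinear) yield zero area and a flag.

## Known limitations

- The region-growing segmenter under-segments when crowns interlock
  (spacing below ~2× the threshold) and cannot split multi-stem clumps;
  recall guarantees hold only for adequately spaced stands.
- DBH is inferred, not measured: errors in the selected growth model
  propagate multiplicatively through the allometry (Ma ~ D²·H^0.6).
- The simplified progressive TIN filter has no spike/negative-blunder
  handling beyond the outlier prefilter and no slope-adaptive tolerance.
- Tasseled-cap defaults are the all-positive vectors described above;
  analyses relying on the signed greenness convention must supply their own
  coefficients.
- At very low pulse densities (≲2 pts/m²) small crowns receive too few
  returns for reliable apexes and the stated detection tolerances no longer
  apply.
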