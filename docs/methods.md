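# Methods

This note documents the models and procedures implemented in `invastack`,
the parameter choices that matter, what the synthetic world does and does
not emulate, and the numerical decisions a user should know before trusting
or extending the results.

## The synthetic world

`world.make_world` builds a gridded environment (unit cells, 0-based
row/col, no CRS) with nine layers mimicking a bioclim-style predictor
stack: mean annual temperature (with a latitudinal gradient plus smooth
noise), temperature annual range, temperature seasonality,
warmest-quarter temperature, annual precipitation (log-normal-like),
precipitation seasonality, warmest-quarter precipitation, a natural
land-use fraction in [0, 1], and soil pH. Land is a thresholded smooth blob
field; connected components of ≥ 20 cells become continents (≥ 2 required).
Warmest-quarter temperature deliberately tracks mean temperature, and
temperature seasonality tracks the annual range, because the two members of
each such pair never share a predictor set — exactly the situation that
motivates running two alternative predictor sets in parallel:

- set 1: temp_mean, temp_range, precip_annual, precip_seasonality,
  land use, soil pH
- set 2: temp_seasonality, temp_warmq, precip_seasonality, precip_warmq,
  land use, soil pH

Within each set, layer noise is regenerated until every pairwise Pearson
|r| over land is ≤ 0.70, in every scenario; `sdm.collinearity_screen`
applies the same strict-exceedance rule (a pair at exactly |r| = 0.70
passes, with a 1e−12 float guard).

**Scenarios.** Five tags: `current`, `mild_r1/r2`, `severe_r1/r2`. Futures
add a uniform temperature shift (defaults +2.0 °C mild, +4.5 °C severe),
multiply precipitation (×1.05 / ×0.90), shift the natural land-use fraction
(+0.05 / −0.10), and hold soil pH fixed. The `r1`/`r2` members add
independent smooth realization noise (amplitude 0.6 °C) to the common
shift — a stand-in for the spread between climate models under one
scenario. The noise amplitude is kept below the mild shift so warming is
positive everywhere.

**Sampling effort.** A sum of Gaussian bumps around survey centres,
strictly positive on land and normalized to 1. The decay scale defaults to
one-third of the domain so that effort varies by a few orders of magnitude
across land without starving whole regions of records — the land-wide but
heavy-tailed character of empirical sampling-intensity indices. The spatial
autocorrelation of real sampling effort is unknown at this grain; the
smooth-bump field is a modelling choice, not a reconstruction.

**Virtual species.** The true suitability is a product of independent
Gaussian responses, S\*(cell) = ∏ exp(−(x_v − μ_v)² / 2σ_v²), rescaled to
max 1 over land — the simplest surface with closed-form truth for recovery
tests. Defaults: niches on (temp_mean, precip_annual); optima uniform
between the 15 % and 85 % land quantiles; breadths uniform in 0.35–0.9 ×
the layer's land sd, which yields suitable-area prevalences (S\* > 0.5)
of roughly 0.01–0.3 of land (median ≈ 0.15), the conventional range for
virtual-species benchmarks. Each species is naturalized on a uniformly
sized random subset of continents. Occurrences are Poisson(λ = 500) raw
records drawn with replacement ∝ S\* × effort, so raw data contain
within-cell duplicates and observation bias by construction.

## Occurrence filtering

Deduplication keeps the first record per cell (idempotent). Environmental
thinning bins each climatic variable of the **active predictor set** into 6
equal-width bins spanning the species' own occurrence range (not the global
layer range — a per-species filtering choice that should be revisited for
real data), with a right-closed top bin and a single bin for constant
variables; one record per occupied multidimensional bin is retained
uniformly at random, seeded per species. Species with < 30 remaining
records are dropped. The order dedup → environmental filter → minimum-record
rule is fixed.

## Pseudo-absence design

The surface range envelope is the per-variable [q, 1−q] quantile box
(linear-interpolation quantiles) of the presence climate, q = 0.025 by
default — the conventional envelope default, exposed in config, since no
single value is canonical. Only the climatic variables of the active set
enter the envelope (an envelope is a climatic range concept; land use and
pH are excluded). Pseudo-absences equal presences in number and are drawn
without replacement (duplicates add no information and would break the
balance semantics) from land cells outside the envelope, excluding presence
cells, with probability ∝ sampling effort — the target-group correction:
background points inherit the presence data's observation bias, so the bias
cancels in the fitted contrast. If too few eligible cells exist the species
is skipped with a message advising a smaller q.

## Models and validation

Four families, each at its library defaults, with seeds fixed for the
stochastic tree methods:

- **linear-logistic** — logistic regression on linear + quadratic terms of
  the standardized predictors. The quadratic expansion is the standard
  SDM-GLM default; a purely linear predictor cannot represent a unimodal
  niche at all.
- **additive-smooth** — binomial GAM with cubic B-spline smooths (df 6).
  The penalty weight is selected on the grid {1, 10, 100, 1000} by held-out
  log-loss on an internal seeded 80/20 split, standing in for the automatic
  smoothness selection GAM libraries apply by default; the winner is
  refitted on all data. Prediction clips new data to the training hull
  (B-spline bases are undefined beyond it).
- **bagged-trees** — random forest, default settings.
- **boosted-trees** — gradient boosting, default settings.

Validation is 4-fold spatial block CV: the 2×2 quadrant partition splits at
the median row/column of the calibration points (presences + PAs); points
exactly on a median go to the lower-index side. Each block is held out
once; the model trained on the other three is scored by the continuous
Boyce index of its predictions at the held-out presences against the
background cells **of the held-out block**. The block-restricted background
matters: a quadrant need not contain the species' full suitability range,
and against a full-landscape expectation even the true suitability surface
scores negative on some folds (measured on virtual species). Folds with no
held-out presences or an undefined index are dropped with a warning; the
model's score is the mean over defined folds, and a model with no defined
fold is rejected. The final projected model is a refit on all calibration
data, carrying its CV score as the ensemble weight source.

**Boyce index.** 101 windows of width 0.1, midpoints evenly spaced so the
windows tile [0, 1], both window endpoints inclusive; windows without
background mass are dropped; the index is the Spearman correlation between
P/E and the midpoints, undefined (a distinct error, not a numeric failure)
for identical predictions, fewer than 3 retained windows, or a flat P/E
curve. Two caveats measured on synthetic data and worth knowing:

- With fixed windows the index is *not* exactly invariant under monotone
  transforms of the predictions (points move across windows); the exactly
  true counterpart, reflection antisymmetry under x → 1 − x, is what the
  tests assert.
- At small presence counts the index is noisy: with ~30 presences even the
  generative truth averages ≈ 0.4 per fold. Cross-validated Boyce values
  from desk-scale simulations are therefore conservative relative to
  data-rich real-world fits.

## Ensemble, threshold, stacking

Models with CV Boyce strictly > 0.6 are retained and weighted ∝ their
scores (weights sum to 1); each predictor set keeps its own ensemble, and a
species with both set-ensembles retained contributes 2 sets × 2 scenarios ×
2 realizations = 8 future projections. The binarization threshold *t\** is
read off the current-conditions ensemble Boyce curve as the lowest retained
midpoint from which P/E ≥ 1 holds for all higher midpoints (the stable
crossing; a `first_crossing` variant is available in config since no
formula is canonical). If the curve never ends at P/E ≥ 1 the species is
flagged and excluded. The same *t\** binarizes every scenario projection of
that species/set; native-range cells are never masked.

Member richness rasters are cellwise sums of binary maps (current: one
member per predictor set; futures: set × realization). The consensus map is
the member mean (rounded half-up only for raster output). Hotspots are
cells with richness strictly greater than ⌊f·M⌋ (M = modelled pool size;
f = 0.10 with 0.05/0.15 sensitivity); future hotspot maps reuse the cut-off
fixed under current conditions. Proportional change and the coefficient of
variation (sd with n−1 over member maps, divided by the mean) are masked —
not zero, not infinite — where current richness or the mean is zero.
Turnover is per-cell Jaccard dissimilarity 1 − |A∩B|/|A∪B| (0 when both
sets are empty), computed per member and averaged; Jaccard satisfies both
endpoint conventions (0 = identical list, 1 = no species shared) but is not
the only index that does, so it is a documented choice. The
continent-restricted sensitivity zeroes each species' maps outside its
naturalized continents before restacking; it can only lower richness.

## Biome space

Cells are classified in (mean annual temperature °C, annual precipitation
cm) space against a packaged nine-polygon approximation of the classic
Whittaker diagram (`whittaker_synthetic.py` — hand-specified rectangles
preserving the biomes' relative positions, not digitized from any published
figure). Assignment is point-in-polygon in ascending biome-id order
(boundary ties take the lowest id); points outside every polygon take the
nearest polygon by Euclidean distance in sd-standardized (T, P) space.
Assignment always uses current climate — biome locations are held fixed
under future scenarios. Richness-weighted density uses a 2-D Gaussian KDE
with the normal-reference (Scott) bandwidth on weighted points, evaluated
on a 256×256 grid; the 95 % contour is the superlevel set holding ≥ 95 % of
the kernel mass on that grid (quadrature), and the centroid is the
weighted mean of the points. Density weighted by richness (rather than raw
cell counts) is the quantity whose centroid shift is interpreted; cell-count
density can be had by passing unit weights.

## Pipeline, seeds, reproducibility

`run_pipeline` executes simulate → filter → pseudo-absences → fit/CV →
ensemble → project (all five scenario tags) → stack → hotspots / turnover /
CV / biome summaries → continental-filter sensitivity, writing TIFF rasters,
CSV tables, a summary JSON and a manifest with SHA-256 checksums of every
artifact. Every stochastic stage derives its seed from the master seed plus
the stage name and species id (CRC-folded into a `SeedSequence`), so two
runs from one config are byte-identical. Per-species failures (too few
records, no eligible PA cells, empty spatial block, no retained model, no
threshold) are logged and skipped, never fatal. The CLI exposes `simulate`,
`run` and `report`; staged fit/ensemble/stack subcommands were deliberately
collapsed into `run` because fitted model objects do not round-trip through
the text artifact formats the pipeline writes.

Default problem sizes — 100×100 grids, 30 species, λ = 500 raw records —
keep a full run in minutes on one core while leaving every stage
non-trivial; the demonstration run in the README uses a 60×60 grid with 8
species.

## What the synthetic world does not show

Passing tests on virtual species demonstrate the pipeline's internal
correctness and its ability to recover known niches under biased,
duplicated, presence-only sampling. They do not demonstrate performance on
real data: the world has no real coastlines or dispersal barriers, its
environmental fields are smooth Gaussian constructs, species' true niches
really are product-Gaussian (the model family is well specified), sampling
bias is a smooth known field, and record counts are orders of magnitude
below real occurrence databases — which matters specifically for the Boyce
index, whose small-sample noise makes desk-scale CV scores conservative.
Real-data mode (GeoTIFF rasters + occurrence CSVs) is plumbing only and is
untested.
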