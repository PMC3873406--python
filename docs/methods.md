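# Methods

## Scope and data model

The package maps abiotically suitable habitat for many species under
current and future climates and aggregates the per-species maps into
richness hotspots. All rasters live on regular lon/lat grids indexed
from the top-left corner (cell-centre convention, floor rule for point
assignment); missing data is NaN in memory and −9999 in float32 TIFF on
disk, with grid metadata in the TIFF description tag. Geodesic areas use
the spherical-strip formula on the authalic sphere (R = 6371.0072 km),
which is within ~0.3% of ellipsoidal areas — negligible against the
percentile constructions built on top.

## Occurrence cleaning

Four steps, each appending `(step, removed)` to a per-species log so
that raw = clean + Σ removals always holds: (1) drop cultivated-flagged
records; (2) keep at most one record per 8 km equal-area cell, using the
Lambert cylindrical equal-area projection (x = R·λ, y = R·sinφ; any
equal-area projection serves since only cell membership matters),
first-seen wins so cleaning is order-stable and idempotent; (3) inside
declared over-collection rectangles, subsample each cell to a density
cap with a seeded RNG — the cap makes an otherwise under-specified
bias-correction step explicit and testable; (4) a strict
more-than-`min_n` record filter partitions species into modelled and
set-aside.

## Predictors

Six layers: MAT (annual mean of (tmax+tmin)/2), MTWM (max monthly tmax),
MTCM (min monthly tmin), AP (annual precipitation sum), PS
(`100·SD(monthly prec)/(1 + mean)`, population SD — the standard bioclim
seasonality convention, with the +1 guarding arid cells), and topsoil
clay fraction passed through unchanged in future scenarios (soil is
assumed static on these horizons). MTCM ≤ MAT ≤ MTWM holds cell-wise by
construction and is asserted in tests.

## Anomaly downscaling

Future climates are built by the anomaly (delta) method: coarse
per-model monthly deltas are interpolated onto the fine grid with a
tensor-product not-a-knot bicubic spline through coarse cell centres
(`scipy` RegularGridInterpolator), which reproduces coarse values
exactly, is exact on constant and linear fields, and extrapolates its
natural polynomial beyond the outermost centres. Below 4×4 coarse cells
it falls back to bilinear with a logged warning. Temperature deltas add;
precipitation supports additive (clamped at zero, clamps counted) and
multiplicative modes — the synthetic generator emits multiplicative
factors, and the algebra choice is recorded on the anomaly stack because
the delta-method literature uses both.

## The maximum-entropy model

A from-scratch L1-regularized Gibbs model over background ∪ presence
cells (duplicate presence records collapse to one per cell, matching the
one-background-point-per-cell rule). Features: 6 linear + 6 quadratic +
15 products, min–max scaled on the training sample; features of a
constant predictor (and products touching it) are dropped with a
warning. Penalties follow the linear/quadratic/product default schedule
— base value interpolated on presence sample size from
`{0: 2.6, 10: 1.6, 17: 0.9, 30: 0.55, 100: 0.05}`, times
`sqrt(var_presence(fⱼ)/m)` (SD floored at 1e-3 on the unit feature
scale), times the user's multiplier (default 1, the calibration this
package targets). The schedule is a configurable table because the
upstream defaults are inherited by reference rather than printed
anywhere authoritative.

The solver splits λ into non-negative parts and runs box-constrained
L-BFGS-B with analytic gradients, restarting (which resets the Hessian
estimate) until the projected KKT residual falls below 1e-6 or a
500-iteration budget is spent; weights below 1e-6 in magnitude are
zeroed. The optimizer is not normative — the contract is the KKT
condition |E_q[fⱼ] − mean_pres[fⱼ]| ≤ βⱼ (equality when λⱼ ≠ 0), checked
directly in the acceptance tests together with a dense grid-search
oracle on small problems. Outputs: the raw relative occurrence rate
`exp(λ·f − log Z)`, its normalization over the projection grid, and the
logistic transform `c·raw/(1+c·raw)` with `c = e^H` (H the fitted
distribution's entropy; the standard prevalence-0.5 calibration).
Projection clamps features to the training [0,1] range and counts
affected cells — the conventional guard against extrapolated responses
under future climates. Thresholding at fixed sensitivity is
rank-invariant to the raw/logistic choice.

## Evaluation

AUC is the Mann-Whitney probability that a presence outscores a
background point (midranks for ties); the fixed-sensitivity threshold is
the largest value keeping ≥ 90% of presence scores (the
ceil(0.9·n)-th largest score), so predicted area is minimal subject to
the sensitivity floor; the omission test is the exact binomial tail
P(X ≥ hits) for a random map covering the observed area fraction. The
screening gate in the source protocol — "omission ... < 0.5" — is
ambiguous between the rate and the p-value, so both are computed and the
default gate applies the rate reading alongside AUC > 0.75. AICc/BIC use
the normalized likelihood at presences with k = the number of nonzero
weights (the convention of the common model-selection tooling for this
model family; flagged undefined when n ≤ k+1). The niche-containment
pre-check builds the convex hull of reference (MAT, AP) points and
counts boundary points as inside.

## Projection and hotspots

Per-model surfaces are averaged cell-wise into a consensus *before*
thresholding (threshold-then-vote exists behind a flag for sensitivity
analysis but is not the default); each species' threshold comes from its
current-climate presence scores once and is reused unchanged for every
future surface. Full dispersal keeps the future mask; no dispersal
intersects it with the current mask, so no-dispersal area ≤ min(current,
future) by construction. Richness is the cell-wise sum of binary masks;
a scope's hotspot is `richness ≥ top-25th-percentile cutoff` (linear
interpolation percentile by default, nearest-rank available; ties
included, so tied surfaces can exceed 25% of scope). Future change
applies the frozen current cutoff to the future surface — applying it to
the current surface reproduces the current hotspot exactly (the 0%
identity, tested). Hotspot mean/SD of richness are computed over hotspot
cells only (sample SD, NaN-flagged when empty/singleton), with the
all-scope-cells alternative available as a flag since the source table
caption supports either reading. Percentile bands label each cell with
the tightest of the top-5/10/15/20/25% cutoffs it reaches; nesting is
guaranteed and tested.

## Synthetic worlds

The generator emulates the statistical structure the pipeline assumes,
not climate physics. Monthly temperature is a seasonal cosine plus a
latitudinal gradient (−0.5 °C per degree by default) plus a smoothed
Gaussian noise field (white noise, Gaussian kernel of `noise_scale`
cells, rescaled to unit variance; identically zero when the scale is 0);
precipitation is a longitudinal gradient with a summer-wet cycle and
log-normal texture; soil is clipped smoothed noise. Species have product
Gaussian niches in MAT and AP only — the other four predictors are
nuisance variables — so parameter recovery has an unambiguous truth.
Presence records are drawn cell-wise proportional to true suitability
*with replacement* (records cluster, as herbarium data do) and jittered
within the cell; a capacity guard rejects requests exceeding the count
of nonzero-suitability cells. Contamination (exact duplicates,
uniformly-placed cultivated records, bias-rectangle oversampling) is
appended in documented proportions. Anomaly ensembles draw one smoothed
field per climate model around the prescribed mean warming;
`warming_sd = 0` makes the ensemble exactly deterministic. Regions grow
by seeded multi-source BFS (contiguous by construction, tiling the
land); climate zones are MAT×AP quantile bins standing in for a discrete
climate classification. Everything is bit-reproducible from its seed.

What passing on these worlds does **not** show: robustness to
georeferencing error, taxonomic noise, non-equilibrium range filling,
collinear predictor regimes beyond the built-in correlations, or real
coastline/terrain structure. The synthetic contamination model is far
cleaner than real aggregator data.

## Problem sizes and defaults

The study conditions the package targets are 10 000 background points,
90% sensitivity, β-multiplier 1, 5 folds, top-25th percentile, 7-model
ensembles. The self-check experiments use: niche recovery on a 100×100
world, 500 presences, 10 000 requested background points, 20
label-shuffled controls (2-fold CV); the warming study on ten 48×48
worlds with 8 species, 200 presences each, 1 500 background points and a
3-model +2.5 °C ensemble — sizes chosen so the full suite and the
reproduction script run comfortably on a single CPU while leaving the
statistical signals (Spearman ρ ≥ 0.9, CV AUC ≥ 0.8, 9/10 sign
consistency) far from their thresholds. The "equatorward hotspot edge"
is measured as the 5th percentile of hotspot-cell latitudes so a few
boundary cells cannot pin the edge at the domain rim.

## Known limitations

- The zone-restriction raster is an input; no real climate
  classification logic is included.
- Background sampling caps at the eligible-cell count with a logged
  shortfall rather than erroring — zone-limited landscapes routinely
  hold fewer than 10 000 cells.
- AICc/BIC compare calibrations of *this* model family only; they are
  not cross-family selection tools.
- Bias thinning is a density cap, one of several defensible readings of
  "removing sampling bias"; thin at a coarser cell than the dedup grid
  or it is a no-op.
- The logistic output inherits the prevalence-0.5 convention; absolute
  values should not be read as occupancy probabilities.
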