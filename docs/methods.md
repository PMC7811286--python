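# Methods

## Problem and scope

`nichespread` implements an end-to-end workflow for estimating a
species' climatically suitable area from presence-only occurrence
records and gridded environmental predictors, and for simulating how the
species could spread across the suitable area from known points of
introduction. The workflow is the one used in invasion-risk assessments
of range-expanding insects: occurrence cleaning and thinning, predictor
screening, a Maxent-style suitability model selected over an enumerated
calibration grid, extrapolation-risk screening (MOP), threshold-based
binarization and consensus, a cellular-automaton dispersal sweep, and
coarse-grid species-richness summaries. All computations run on
synthetic virtual-species landscapes with known ground truth; no
external data downloads are involved.

## Grid model and geometry

All layers live on one regular geographic grid of square cells (WGS84
lon/lat). Cell (0, 0) is the upper-left cell and cell centers sit at
`origin + (index + 0.5) * cell_size`; every point-in-cell decision uses
cell centers and half-open cell intervals, so a point on a shared edge
belongs to exactly one cell. Distances on the sphere use the haversine
formula with a fixed Earth radius of 6371.0 km, which is accurate to a
fraction of a percent at the 50–500 km scales the workflow uses.
Rasters are exchanged as single-band GeoTIFFs; the reader/writer is a
small purpose-built layer over `tifffile` carrying the standard geo tags
(pixel scale, tiepoint, WGS84 geokeys, nodata). Nodata cells are
excluded from all statistics and treated as unsuitable and
non-traversable downstream.

## Occurrence handling

Cleaning removes records with missing or out-of-bounds coordinates,
exact duplicates of `(species, lon, lat)` after rounding coordinates to
six decimals (~0.1 m), records falling in no country polygon (at sea),
and records whose declared country disagrees with the polygon containing
them. The operation is idempotent and logs per-rule removal counts.

Two thinning schemes prepare alternative calibration data sets:

* **Distance thinning** (default minimum 50 km) visits records in a
  seed-shuffled order and keeps each record iff it lies at least the
  minimum great-circle distance from every record already kept. The
  output has all pairwise distances above the minimum and is maximal
  under its visit order. The greedy-on-random-order construction is a
  deliberate choice: the constraint itself does not identify a unique
  subset, and a seeded greedy pass is reproducible and unbiased with
  respect to record order.
* **Country-density thinning** takes explicit per-country target counts
  and subsamples each listed country uniformly at random (seeded) down
  to its target, leaving unlisted countries untouched. Targets are
  explicit inputs rather than derived from a reference-density formula,
  which makes reductions such as 30 -> 6 records exactly reproducible.

## Predictors

The calibration area M is a fixed-radius great-circle buffer (default
500 km) around the thinned occurrences, rasterized by cell center.
Two predictor treatments are supported:

* **Correlation filtering**: variables are examined in a user-supplied
  priority order (the mechanism for encoding expert preference) and
  kept iff their absolute Pearson correlation over M with every
  previously kept variable is at most `r_max` (default 0.85).
* **PCA**: a standardized (correlation-matrix) PCA is fitted on the
  cells of M only; the frozen centering, scaling and rotation are then
  applied to the full extent so that component scores are directly
  comparable between the calibration region and any projection region.
  Correlation-based PCA is used because the predictors mix units;
  component signs are fixed so each component's largest-magnitude
  loading is positive, making the decomposition deterministic. The
  pipeline retains the leading components reaching 95% cumulative
  variance (at least two).

## Suitability model

The model estimates a Gibbs density over the background cells of M,
`P(cell) = exp(lambda . f(cell)) / Z`, by minimizing the L1-regularized
convex objective

```
-mean_presence(lambda . f) + log sum_background exp(lambda . f)
    + sum_j beta_j |lambda_j|
```

Features are built from variables rescaled by their calibration-
background range: linear (l), quadratic (q), pairwise products (p),
threshold steps (t, 10 equally spaced knots per variable) and forward
hinges (h, 20 knots per variable). Per-feature penalties are
`beta_j = rm * c_class * sd_j(background) / sqrt(n_presences)` with
class costs l/q 0.05, p 0.1, t 1.0, h 0.5. This transparent rule
preserves the ordering controlled by the regularization multiplier `rm`;
it is a stand-in for the versioned default-regularization tables of
Maxent releases and no bit-compatibility with any Maxent build is
intended or claimed.

The optimizer is L-BFGS-B on the split formulation `lambda = u - v`,
`u, v >= 0`, which turns the L1 penalty into a smooth linear term under
bound constraints. The problem is convex, so the solver is
deterministic up to tolerance; a multistart test verifies agreement of
final objectives within 1e-5. Note that the linear and quadratic
features of one variable are strongly collinear, so near-null data can
carry large opposing weight pairs whose net effect on the density is
negligible; null behavior is therefore assessed on the fitted
distribution (entropy within 1% of the uniform maximum), not on
individual weights.

Output scales: *raw* is the density normalized to sum to 1 over the
background; *cloglog* is `1 - exp(-exp(H) * raw)` with `H` the entropy
of the raw distribution, an index in [0, 1]. Transfers support free
extrapolation (E), clamping of each variable to its calibration range
(EC), and no extrapolation (NE), where any cell with an out-of-range
variable becomes nodata. NE masks such cells rather than zeroing them:
the workflow pairs NE with MOP trimming, and masking is the
conservative reading.

## Calibration, evaluation, selection

Candidates enumerate every combination of regularization multiplier
(default 0.10, 0.25, 0.50, 0.75, 1, 2, 3, 4, 5, 6), feature-class set
(lq, lp, lqp, qp, q, lqpt, lqpth, lqph) and predictor subset of size at
least two — 4,560 candidates for 6 predictors, 880 for 4. The minimum
subset size of two is the only reading consistent with those totals
(2^6 - 6 - 1 = 57 and 2^4 - 4 - 1 = 11 subsets respectively).

Evaluation uses k = 5 independent random 50/50 train/test splits (not a
partition). Per candidate and split:

* **Partial ROC.** The curve of sensitivity against proportion of area
  predicted present is built over all distinct landscape suitability
  values; the statistic is the ratio of the model's partial area to the
  1:1 line's partial area over the sensitivity band >= 1 - E (E = 0 is
  the degenerate "no restriction" convention and reproduces the full
  trapezoid AUC). The reported `mean_auc_ratio` is the mean over
  bootstrap resamples of the test points (50% with replacement, 500
  replicates by default). Significance is assessed against a
  landscape-matched Monte Carlo null: samples of the test-set size drawn
  from the landscape's own suitability distribution are scored
  identically, and the p-value is the add-one fraction of null ratios
  at least as large as the observed full-sample ratio. The customary
  convention of counting bootstrap ratios below 1.0 is *not* used: the
  band restriction inflates the ratio above 1 even for random test
  points at these sample sizes (for 10-point resamples the band retains
  only the sensitivity-1 plateau, where the curve lies above the
  diagonal by construction), which makes the below-1 count reject
  almost always under the null. The landscape-matched null restores the
  nominal type-I error (simulated rejection ~0.04–0.06 at alpha = 0.05)
  while leaving the statistic itself unchanged.
* **Omission rate** at E = 5%: the fraction of test suitabilities
  strictly below the modified least-presence threshold of the training
  half (strict inequality, consistent with the >= rule of
  binarization).
* **AICc** from the candidate refitted on all occurrences, with
  k = the number of nonzero weights and the likelihood taken from the
  raw output normalized over the prediction landscape;
  `n - k - 1 <= 0` or a zero-density occurrence yields +infinity.

Selection keeps candidates with p < alpha and omission < E, recomputes
delta-AICc within that filtered set from its minimum, and retains
delta <= 2. The delta recomputation happens after the significance and
omission filters (the filters define the candidate pool from which the
best model is meaningful); an empty selection is a valid outcome and
halts the affected pipeline scheme with a logged reason.

Final models refit each selected configuration on all occurrences with
10 bootstrap replicates (presences resampled with replacement,
background fixed). Each replicate is binarized at the modified
least-presence threshold — the order statistic at 0-based index
`floor(E * n)` of the ascending calibration suitabilities, cells
suitable iff value >= threshold, which bounds calibration omission by
E + 1/n — and must predict every independent (invaded-region) record to
be retained. Consensus layers are the median of per-configuration
medians (continuous) and the cellwise sum of replicate binaries
(agreement count).

## Extrapolation risk (MOP)

Each projection cell is scored by its mean Euclidean distance — on
variables standardized by the reference range, so axes are commensurate
— to the nearest `ceil(p_nearest * N_ref)` reference cells (default 5%);
similarity is `1 - distance / max(distance)`. Cells with any variable
outside the reference range form the strict-extrapolation mask, which
is exactly the union over variables of the out-of-range indicators.
Trimming deletes strict-extrapolation cells from binary suitability
maps; low-similarity (combinational) areas are left in place by
default, with a similarity floor available for the stricter reading.
Distances are exact (all reference cells) up to an optional seeded
subsampling cap of 10,000 reference cells.

## Dispersal simulation

The automaton is deterministic and monotone on a binary suitability
grid: a cell, once occupied, stays occupied, and at each step every
suitable cell within Chebyshev distance d (a generalized Moore
neighborhood) of an occupied cell becomes occupied. The connectivity
parameter d is read as a neighborhood *radius*, the only reading under
which the ladder 1, 2, 4, 8, 10, 12 behaves as a distance. There is no
extinction, carrying capacity or stochastic colonization; the steady
state is therefore exactly the union of radius-d connected components
of suitable cells containing the seeds, which the tests verify against
an independent flood fill. Runs stop at the fixed point or at the step
cap (default 200, ample for desk-scale grids whose diameter is far
smaller).

The scenario sweep crosses connectivity radii (default 1, 2, 4, 8, 10,
12) with 10 equidistant threshold levels `E_i = 0.03 + 0.07 i / 9`
(3–10%), re-binarizing the continuous consensus at each level — 60
scenarios — and reports the percentage of scenarios in which each cell
was reached. MOP-trimmed and nodata cells are unsuitable and
non-traversable.

## Species richness

Multi-species occurrences are binned into a coarse grid (default one
degree) with half-open cell intervals; the presence–absence matrix
records species-by-cell incidence and richness is its row sum. Richness
is invariant to record duplication and order.

## Synthetic data

The generator produces every input with known ground truth:

* **Environment**: seeded mixtures of low-frequency sinusoids plus
  Gaussian-smoothed noise, standardized per layer; the default is a
  60 x 60 grid of 10-arcminute cells (a 10 x 10 degree mid-latitude
  window), three variables, length scale 6 cells. The surfaces are
  spatially autocorrelated and mutually distinct but do not attempt to
  emulate the covariance structure of real bioclimatic archives.
* **Truth**: `logistic(sum_j a_j x_j + b_j x_j^2 + c)` — unimodal in
  each variable with a negative quadratic term, so an lq-class model
  can represent it exactly on the link scale. The default species
  responds to two of three variables (the third is a nuisance) with
  moderate prevalence.
* **Countries**: a seeded Voronoi partition of the extent (five
  countries by default), the simplest polygon set supporting
  country-based cleaning and density thinning.
* **Occurrences**: 200 records by default, sampled with probability
  proportional to truth x per-country sampling weight (one country
  oversampled 10:1, emulating uneven reporting effort), each point
  jittered uniformly within its cell so that sub-cell geometry is
  exercised by distance thinning. Five independent records are placed
  in high-truth cells to play the role of invaded-region detections.
* **Invasion fixture**: a 40 x 40 landscape whose suitable area forms
  two rectangular patches separated by a three-cell unsuitable channel;
  the nearest suitable cells are four columns apart, so the automaton
  bridges the gap iff d >= 4. The fixture documents this bridging
  radius and seeds the western patch.

Because the generator's surfaces are smooth, its niche exactly
representable, and its sampling bias purely multiplicative by country,
passing tests demonstrate the correctness and internal consistency of
the machinery — not predictive skill on real archives with observation
error, spatially varying effort within countries, or niches outside the
model's feature space.

## Problem sizes and numerical choices

The default test and reproduction runs use desk-scale sizes chosen as a
deliberate design point: 60 x 60 grids, 200 occurrences, a reduced
candidate grid (multipliers 0.5/1/2, class sets lq/lqp) for the
recovery studies, 300–500 bootstrap replicates for partial ROC, 50
random 40 x 40 landscapes for the automaton cross-check, and five
virtual species for recovery. The full enumeration grid (10 multipliers
x 8 class sets) is exercised where only counting is at stake. Optimizer
tolerance is 1e-10 (ftol) with a 10,000-iteration cap; weights below
1e-10 are collapsed to zero; nonzero-weight counting for AICc uses a
1e-8 cutoff. Ties in thresholds resolve via the >= suitability rule.
Degenerate inputs (constant landscapes with constant test values,
empty selections, unsuitable seeds) return flagged results or logged
halts rather than exceptions wherever the workflow can meaningfully
continue.

## Known limitations

* The regularization rule is a transparent stand-in; absolute AICc
  values and selected-weight counts will differ from any specific
  Maxent release.
* The partial-ROC p-value uses a landscape-matched Monte Carlo null
  (see above); studies comparing against the below-1 bootstrap count
  will see systematically larger (better-calibrated) p-values.
* MOP reports strict extrapolation exactly but does not decompose
  combinational novelty by variable subset.
* The dispersal model ignores propagule pressure, long-distance jumps
  and human-aided transport; occupancy percentages are scenario
  agreement, not probabilities.
* Projected (non-geographic) coordinate systems, multi-band rasters and
  larger-than-memory tiling are out of scope.
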