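# Methods

## Model

The regressor is a first-order Takagi–Sugeno fuzzy system. Each of the
`k` rules carries one generalized-bell membership function per input
feature, `μ(x) = 1/(1 + |(x−c)/a|^{2b})` with width `a > 0`, shape
`b > 0` and centre `c`; rule firing strengths are products of memberships
across features, normalised to sum to one; each rule contributes a linear
consequent `p0 + Σ p_i x_i`; the output is the normalised-weight mixture.
The prediction is therefore a convex combination of the rule consequents,
which bounds it between the smallest and largest rule output at any point.

All parameters live in one flat vector of length `m·k·3 + (m+1)·k`
(packing order: all widths rule-major, all shapes, all centres, then
per-rule consequent blocks `[p0_j, p_j1..p_jm]`). RMSE is computed with
the radical applied; the consequent inner sum runs over the features of
each rule, which is the only reading consistent with `(m+1)` consequents
per rule in the count formula.

Degenerate inputs: if all firing strengths fall below 1e-12 (a point far
outside every membership support), the normalised weights fall back to
uniform `1/k` rather than dividing by ~0.

## Fitting

The objective is the RMSE on a hold-out validation set (default 30% of
the rows; `floor(0.7·n)` training rows, which maps 158 plots onto a
110/48 split). Search ranges per feature with observed range R: widths
in `(0, 2R]` (floored at 1e-3·R), shapes in `[0.5, 5]` to exclude flat and
needle-shaped memberships, centres padded 10% beyond the data range, and
consequents within ±10× the target scale. The search runs in the unit box
and is mapped affinely onto these bounds.

The global phase is atom search optimisation: atoms (candidate parameter
vectors) interact through a Lennard-Jones-style force whose repulsive and
attractive parts cancel at `r = 2^{1/6}σ ≈ 1.12σ`, and better atoms get
larger masses `M_i = exp(−(Fit_i − Fit_best)/(Fit_worst − Fit_best))`, so
they move less and anchor the population. Two dynamics are implemented:

* **adaptive** (default): interaction restricted to a shrinking K-best
  neighbour set, reduced distances clipped to the near-equilibrium band
  `[1.1 + 0.1·sin(πt/2T), 1.24]` with a per-atom length scale set by the
  distance to the K-best centroid, a depth weight
  `α(1−(t−1)/T)³e^{−20t/T}` (α = 50), and a drift force
  `β e^{−20t/T}(x_best − x_i)` (β = 0.2). These refinements are what make
  the dynamics convergent; on a 5-d sphere the best objective drops ~20
  orders of magnitude in 200 iterations.
* **literal**: the bare pairwise force at fixed σ = ε = 1 with `a = F/m`.
  In a normalised unit box nearly every atom pair sits below the
  equilibrium distance, so the population is purely repulsive and
  disperses to the bounds; this mode exists to make the primitive
  dynamics traceable, not to fit models.

The fit is **memetic** by default (`polish="deep"`). The validation-RMSE
surface of the ANFIS has narrow, curved valleys (empirically, attraction
basins with radius ~0.05–0.1 in the unit box at 26 dimensions) that
population moves cannot descend at realistic budgets, so:

1. the population is seeded with a fuzzy-c-means warm start (centres from
   clusters, widths from membership-weighted dispersions, shapes at 2,
   consequents by per-cluster weighted least squares) plus random **rule
   placements** whose consequents are conditionally optimal — for frozen
   memberships the consequents enter linearly, so the training-optimal
   consequents are a weighted least-squares solve per rule;
2. every initial atom is refined by bounded L-BFGS-B (the objective is
   smooth in the parameters);
3. during the search the incumbent is re-polished periodically and
   reinjected into the population (Lamarckian step);
4. a final iterated-local-search phase perturbs the incumbent with
   log-uniform step sizes and polishes each candidate.

The conditional least-squares step is used only to *seed* atoms; the joint
search over memberships and consequents remains with the optimiser (this
is not an alternating least-squares/backprop training scheme). Budgets:
`polish="light"` does a single final polish (used by the one-vs-rest
classifier and cheap wrapper fitnesses); `polish="none"` is the bare
population search. With the defaults, refitting data generated from a
known 2-rule, 3-feature model at 5% relative noise reaches a validation
RMSE of ~4% of the target SD across seeds (~20 s per fit on one CPU).

Because the selection criterion is itself the validation RMSE, a residual
optimisation bias of roughly `sqrt(1 − d/n_val)` remains: on a pure-noise
target with d = 26 and 120 validation rows the deep fit settles ~15–25%
below the target SD. This is measured, expected behaviour of the
validation-objective design, not signal.

## Predictor variables

The 42-variable registry holds the four reflectance bands, VV and VH, four
polarisation combinations (average, difference, product, VV/VH ratio) and
32 spectral indices. Index formulas are data-driven (name → expression
over B, G, R, N with soil-line constants a = 1.22, b = 0.03) and can be
serialised to JSON, overridden or extended. Division is rewritten through
a guard so zero denominators yield masked (NaN) cells instead of silently
propagating infinities. Two special cases: `CIRED_EDGE` uses the `N/R − 1`
surrogate because a 4-band sensor has no red-edge band, and `VIN` (`N/R`)
is registered as an extra variable outside the 42-band stack because
selection outputs occasionally name it. The polarisation combinations are
computed on the σ° dB values as the variable names imply; a linear-power
mode is available behind a flag, since the convention is genuinely
ambiguous for products and ratios of logarithmic quantities.

Plot extraction averages each band over the axis-aligned square window
whose area matches the plot (side `√area`, centred on the plot), weighting
cells by their exact fractional overlap; it agrees with a dense-supersample
oracle to ~1e-3. Plots falling outside the raster are dropped with a
warning. Bilinear resampling onto the reference grid masks any output cell
whose 2×2 support touches nodata.

## Allometry

Per-tree biomass is `a·DBH^b` in kg (DBH in cm) from a five-species
mangrove registry (two *Avicennia*, two *Rhizophora*, one *Bruguiera*);
plot density converts as `Σ kg / 1000 · 10000/area_m²` → Mg ha⁻¹. The
kg-per-tree convention is the one that makes simulated stands at ~2,830
stems ha⁻¹ and DBH 6.9–19 cm land in the observed 40–340 Mg ha⁻¹ envelope.
A genus-level fallback (mean of congeners' coefficients) is available
behind a flag for unspeciated records.

## Feature selection

* **ReliefF** (regression form): for every probed row and its k = 10
  nearest neighbours (normalised Manhattan distance), accumulate
  attribute-difference and target-difference statistics with
  rank-exponential neighbour weights;
  `W[A] = N_dCdA/N_dC − (N_dA − N_dCdA)/(m − N_dC)`. All rows are probed
  by default, making the ranking deterministic.
* **Correlation ranking**: |Pearson r| with the target; zero-variance
  features score 0.
* **CFS**: best-first forward search maximising
  `k·r̄_cf / sqrt(k + k(k−1)·r̄_ff)`; matches an exhaustive merit search on
  small tables; guarded to return at least one feature.
* **GA wrapper**: binary chromosomes over the feature list; tournament
  selection, single-point crossover, bit-flip mutation at 1/L, elitism 2,
  population 20 × 30 generations by default. The fitness is the
  validation RMSE of a *budgeted* fit that is tuned on the training rows
  only — tuning the wrapper model against the scoring rows would reward
  every extra feature as free capacity. The fitness seed is derived from
  the mask bits so repeated queries are identical, and results are
  memoised (no mask is ever evaluated twice). After the GA, a
  steepest-descent pass over single (and, for short chromosomes, paired)
  bit flips polishes the best mask into a local optimum of the same
  fitness.
* **Incremental screen**: add features in rank order, stop after a
  patience of consecutive non-improvements, return the best prefix.

## Evaluation

Hold-out splitting is seeded and uses the floor rule above. R² is computed
about the observed mean and may be negative (worse than the mean
predictor). Model comparisons use the two-sided Wilcoxon signed-rank test
on paired absolute validation errors (exact null for n ≤ 25 without ties,
normal approximation otherwise). Benchmarks run on identical splits:
grid-searched RBF-SVR (C ∈ {0.1,1,10,100}, γ ∈ {0.001,…,1}, standardised
inputs), a single-hidden-layer MLP, a 500-tree random forest, and a
random-subspace ensemble (unpruned trees on 75% feature subsets without
row bootstrap). Random-subspace regression carries an irreducible
feature-exclusion bias on smooth truths — trees that draw a subspace
missing an informative feature contribute systematically biased
predictions — which plateaus its R² near 0.85 on data where every other
model exceeds 0.9; the test suite asserts the measured bounds rather than
a uniform one.

Thematic accuracy: producer's accuracy is per-class recall, user's
accuracy per-class precision, overall accuracy the trace ratio, and
Cohen's κ `(p_o − p_e)/(1 − p_e)` with the product-of-marginals chance
agreement.

## Mapping

Map prediction applies the fitted estimator to every unmasked cell of the
stack, so raster and tabular predictions agree bitwise. Classification is
one-vs-rest indicator regression with argmax (ties resolve to the lowest
class code) over externally provided segments; the class map is rasterised
by segment id. The area cross-tab bins the biomass map at 50/100/150/200
Mg ha⁻¹ (five ranges, configurable) and reports hectares per (class, bin)
from the cell size, with totals that exactly conserve the jointly unmasked
area.

## Synthetic data

The generator emulates the study conditions rather than any physical
radiative transfer. The latent AGB field is smoothed Gaussian noise
rescaled to 40–340 Mg ha⁻¹. C-band backscatter follows
`s_min + (s_max−s_min)(1 − e^{−AGB/λ})` plus 0.5 dB noise with λ = 60
Mg ha⁻¹, spending most of its sensitivity by 50–70 Mg ha⁻¹ — the
saturation domain that makes C-band biomass retrieval hard; NIR rises and
red falls monotonically with canopy so NDVI-type indices track biomass.
Plots (158 by default) draw Poisson stem counts at 2,830 stems ha⁻¹ on
100 or 1,000 m² plots, a Rhizophora-dominated species mix, and DBH values
around the mean diameter that makes the expected allometric biomass match
the latent field at the plot centre; inventories are redrawn (up to 25
times) when sampling noise would spill outside the observed envelope,
mimicking a campaign that only reports plots within it.

What passing tests on these data do **not** show: robustness to
atmospheric or radiometric calibration error, speckle, co-registration
error, species misidentification, allometric model error, or plot GPS
error — none of which the generator emulates. Real-data performance is
expected to be far below the synthetic figures.

Tabular recovery datasets (`make_anfis_dataset`) draw a valid random
rule base (widths 0.15–0.45, shapes 2, centres 0.15–0.85, consequents
±2 over the unit feature cube) and add Gaussian noise specified relative
to the clean target SD, so "5% noise" means a noise floor at 5% of signal.

## Problem sizes and determinism

Test-suite runs use deliberately small instances — 48–64-cell scenes,
80–600-row tables, budgeted optimiser settings — chosen so the full suite
completes in a few minutes while still exercising every code path at the
fidelity the assertions need; the recovery and wrapper-optimality checks
are the two deliberately expensive tests (~20 s each). All randomness
flows through explicit `numpy` Generators; identical seeds give
bit-identical fits, selections and reports.

## Known limitations

* The classifier's one-vs-rest indicator scores are not calibrated
  probabilities.
* The GA wrapper's local-search pass makes the returned mask a local
  optimum of the budgeted fitness, but global optimality is only verified
  against exhaustive enumeration on small feature counts.
* The adaptive optimiser's α and β defaults (50, 0.2) follow the original
  method's recommendations; they were not re-tuned per problem.
* Raster I/O uses plain multi-band TIFF with georeference metadata
  embedded as JSON in the image description tag; files are readable
  anywhere but carry no formal GeoTIFF tags.
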