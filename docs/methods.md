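# Methods

This note documents the models, the synthetic study conditions, the
numerical choices and the known limitations of `nichetransfer`.

## The maxent niche model

A presence–background maxent model is a Gibbs distribution over the
landscape's background cells, q_λ(x) ∝ exp(λ·f(x)), fitted by
minimizing the L1-penalized negative presence log-likelihood

    φ(λ) = −(1/m) Σ_presences λ·f(x)
           + log Σ_background exp(λ·f(b))
           + Σ_j β_j |λ_j|.

φ is convex, so the optimizer choice only affects speed, never the
optimum: we split λ into positive and negative parts (turning the L1
term into a smooth bound-constrained problem) and run L-BFGS-B with a
small random start (the `random_state`); random restarts reach
objectives within 1e-4 of each other, which a test asserts. At β = 0
the stationarity condition is exact moment matching, E_q[f_j] =
presence mean of f_j; this is the contract the unit tests pin against
an independent 1-D root-finder.

**Features.** Covariates are scaled to [0, 1] by their training range
(presences ∪ background). Classes: linear, quadratic, pairwise
products, and hinge features max(0, (v − k)/(v_max − k)) at evenly
spaced knots. The default knot count is 50 per variable; the pipeline
runs in this repository use 10, ample for a 4-variable synthetic
landscape with smooth Gaussian niches. Which classes are active
defaults to the sample-size schedule (fewer than 10 presences: linear
only; < 15 adds quadratic; < 80 adds hinge; otherwise all), overridable
via `feature_classes`.

**Regularization.** β_j = r(m) · sd_j / √m, where sd_j is the feature's
standard deviation over the m presences (floored at 0.01 so
presence-constant features still carry a penalty) and r(m) is the
published per-class multiplier interpolated in m: linear/quadratic
(0, 1.3), (10, 0.8), (17, 0.5), (30, 0.25), (100, 0.05); products
(0, 2.6) … (100, 0.05); hinge 0.5 throughout. A scalar `beta` overrides
everything (used by tests to probe the β = 0 and β → ∞ limits).

**Projection.** Applying a fitted model to another decade clamps
covariates to their training range (recorded in a clamp mask) and
renormalizes exp(λ·f) over the target extent. All downstream statistics
are rank- or threshold-based, so the normalization is cosmetic; a
property test asserts AUC invariance under monotone transforms. The
logistic output exists purely for display.

## The decadal transfer design

For D decades each species gets D interpolative models (Im, trained
and evaluated within one decade) and D(D−1)/2 forward projections (Em,
source < target), i.e. D(D+1)/2 tasks; 5 decades and 37 species give
the 15/555 totals the run-plan test asserts. Backward projection is
deliberately unsupported.

Each Em(s→t) is validated on decade-t data — scored at decade-t's
train/test presence cells and background — and compared against the
target decade's own Im(t), which is treated as the better
representation of the contemporary range. TI_H uses test AUCs by
default (`use_train_auc` switches). Binary maps come from the equal
sensitivity–specificity threshold computed on each model's own scores
(presences vs background of the evaluation decade); RRS and OI compare
the two independently thresholded maps. Specificity is computed against
the background sample, since a presence-only design has no true
absences.

One detail matters for interpreting zero-drift results: under identical
climates, decade-t presences largely coincide with the cells an Em's
source-decade training presences occupied, so an Em's "test" AUC
behaves like a training AUC while Im(t)'s test AUC pays a genuine
holdout penalty. TI_W therefore sits slightly *above* 1 by roughly
Im's overfit gap (AUC_train − AUC_test). With the default study
conditions that gap averages ~0.02–0.04 and the species-mean indices
stay within 5 % of 1, which is what the zero-drift acceptance check
asserts; at much smaller survey sizes the gap — and the upward bias —
grows.

## The synthetic survey world

The generator emulates the ingredients of a decadal citizen-science
niche-modelling study, with every stochastic step drawn from a stream
keyed by (seed, operation, entity) so adding a species never perturbs
another.

**Climate.** Each variable is white noise smoothed by a Gaussian kernel
(`spatial_corr_length` = 6 cells) and standardized; designated pairs
are mixed to a target correlation. Decades differ by a cumulative
mean shift with per-decade increments N(0, `decadal_drift_sd`), applied
through a taper 1 − ((v − mid)/halfrange)² that vanishes at the
variable's range limits. Interior cells therefore drift by roughly the
drawn increment (the realized mean shift is ~0.7× it) while every
decade's values stay inside the base range cell-for-cell — the decades
are climatically analogous *by construction*: no novel climates, no
clamping, matching the premise of the transfer design. A test asserts
the MESS surface of every later decade against the first decade's
cell-complete reference is nowhere negative (cells at the reference
extremes score exactly 0, i.e. boundary, not novel).

**Species.** True suitability is a Gaussian kernel of the decade's
climate around a niche center anchored at a real cell's climate vector
(narrow endemics get half the niche breadth). Occupancy is the top-m
suitable cells among those passing a fixed per-cell rarity mask, with
m = round(prevalence × n_cells × trend_factor^decade) — a deterministic
variant of "suitability exceedance plus thinning" chosen so occupied
counts hit the prevalence target exactly and population trends are
monotone by construction. Archetype defaults: widespread prevalence
0.25, narrow 0.035 (under the 0.05 narrow threshold); "rare" species
get 0.3× the occupancy density and 0.5× the detectability of "common"
ones, implementing both readings of rarity at once. Trend factors are
1.2 (increasing) and 1/1.2 (decreasing) per decade.

**Surveys.** One candidate circle per 5×5-cell block with a jittered
center, 80 % active, radius 2 cells (a 15-mile-diameter circle at ~5 km
cells), surveyed every year of every decade (10 years/decade, 5
decades). Per circle-year-species: detection with the species'
detectability if any occupied cell lies in the circle, otherwise a
false detection with `misid_rate` (default 0.01 — the error mode the
5 % filter exists to remove). The default 120×120 grid with ~460
circles was chosen once as a scaled-down analogue of a continental
survey: large enough that widespread species yield hundreds of thinned
presences and narrow species still clear the 4-presence modelling
floor.

**What the world does not emulate** — and hence what passing tests do
not show about real data: realistic geography and topography, seasonal
movement, spatially biased survey effort, habitat change decoupled from
climate, biotic interactions, and dispersal limitation. The climate
drift is spatially uniform in its tapered form, unlike real
heterogeneous change.

## Occurrence processing

The misidentification filter removes a (circle, species) pair when its
detections span strictly fewer than 5 % of that circle's *surveyed*
years, counted over the full multi-decade record (the "at that survey
site" reading); it is idempotent. Decadal binning keeps presence-only
records; thinning assigns each presence to the cell holding its
circle's center and deduplicates per cell. Background cells are drawn
uniformly — without replacement when the extent has at least n cells,
with replacement otherwise. The test split holds out
round-half-up(0.25 n) presences; species-decades with fewer than 4
thinned presences are skipped and logged. The repeated-split averaging
option is off by default: one random 75/25 split per model.

## Climate operations

Bioclim variables follow the canonical definitions with quarters as any
3 consecutive months, December–January wrap allowed, ties broken toward
the earliest start month; bio4/bio15 use population SD by default
(`sd_ddof=1` switches convention). Equivalence to a straight-loop
oracle at 1e-9 is asserted over random monthly series.

VIF is 1/(1 − R²) from regressing each variable on the rest. Two screen
semantics are exposed because a "0.9 threshold" only makes sense as a
correlation: `pairwise-correlation` (default) iteratively drops the
higher-VIF member of the worst |r| > threshold pair; `stepwise-VIF`
drops the max-VIF variable while above threshold. Ties break toward
the lowest column index; constant columns and exactly collinear sets
(infinite VIF, invisible to a pairwise screen) are flagged up front.
The screen is run on values sampled at presence + background points;
cell-complete mode is just passing all cells.

MESS follows the percentile-similarity construction: with f the
percentage of reference values strictly below a cell's value, S is
100(v−min)/(max−min) at f = 0, 2f for f ≤ 50, 2(100−f) for f < 100,
and 100(max−v)/(max−min)+100 at f = 100; the cell score is the minimum
over variables and negative values mark novel climate. A constant
reference variable yields 0 on the constant and a logged −inf sentinel
off it.

## The background-extent artifact experiment

Each narrow-ranged species is fitted twice with identical presences,
background count and seed policy: once with background drawn from the
full extent, once from only the rectangular regions ("states", default
10×10-cell blocks) containing at least one presence. Because a
full-extent background is climatically distant from a narrow range,
the full-extent AUC is inflated relative to the reduced-extent AUC; the
experiment reports both plus a paired t-test (Welch fallback if pairing
breaks). Species whose reduced extent equals the full extent are
flagged uninformative. On 12 clean synthetic narrow species the mean
inflation is ≈ 0.2–0.3 AUC with t ≈ 7–11 — the direction the design
predicts.

## Trait analyses

The 37-species trait fixture carries range class (WC/WR/NEC/NER, with
derived wide/narrow and common/rare collapses), migratory status,
habitat (including the uncategorized "O" level retained verbatim),
conservation status, population trend (two codings, because published
assessments conflict for Field Sparrow and Eastern Meadowlark), a
common-birds-in-decline flag, and a 4-level body-mass category.

The battery: Pearson chi-square without continuity correction (zero
marginals dropped with a warning); Gaussian-identity GLMs with
single-term deletion — full least-squares fit, one refit per term,
SS = RSS_reduced − RSS_full, F = (SS/df_term)/(RSS_full/df_resid), with
a chi-square analysis-of-deviance mode behind a flag and AIC on the
`extractAIC` scale n·log(RSS/n) + 2·edf (the Gaussian constant is
omitted); Wilcoxon rank-sum (exact when n1+n2 ≤ 12 and tie-free, else
tie-corrected normal); Kruskal–Wallis with tie correction. No
multiple-testing adjustment is applied anywhere, by design.

Power and size of the battery are checked at the species-summary level:
a built-in rarity effect of 0.08 on mean AUC against residual noise of
SD 0.04 (the scale of between-species AUC scatter in the pipeline's own
summaries) must be recovered in ≥ 80 % of 50 replicates, the
no-effect false-positive rate must stay ≤ 10 %, and the Kruskal–Wallis
null rejection rate at 3×30 observations must sit in 5 % ± 1 % over
10⁴ simulations.

## Numerical choices and degenerate inputs

- Optimizer tolerance 1e-8 on the objective, 500 iterations by default;
  hitting the cap returns the model with a warning flag.
- Equal sensitivity–specificity threshold: candidates are the sorted
  unique scores, ties broken toward the lowest threshold.
- Swets grades use the standard orientation (higher is better), each
  bin closed on the right of its lower bound (AUC = 0.9 grades "good").
- Zero-variance paired differences report an infinite t with a warning
  rather than raising; zero-variance GLM responses report SS = 0,
  p = 1.
- Zero-area binary ranges are errors naming the offending map.
- Background sampling from a single-cell mask returns n copies of that
  cell.
- Raster I/O is plain-text ASCII grid (header + matrix); grids are
  float row-major with row 0 at the top.

## Problem sizes

Test and acceptance runs use a 120×120 world (100×100 for the extent
experiment), 12 species, 5 decades, 1500–2000 background points and
10 hinge knots per variable; the full pipeline at these sizes runs in
tens of seconds. These sizes were chosen as the smallest at which the
asymptotic behaviour the indices measure (overfit gaps of a few
hundredths, stable AUC ranks) is visible; all are config knobs.

## Known limitations

- The maxent implementation is contract-compatible (objective, moment
  matching, clamping, raw/logistic outputs) but not byte-compatible
  with the historical Java program; categorical and threshold features
  are not implemented.
- The OI/RRS comparison thresholds Em on its own scores; the
  alternative (re-using Im's threshold) is not exposed.
- Area is cell count: the synthetic grid is equal-area, and the
  cell-size weighting hook is a stub for real projections.
- The 5 % filter interpretation (full record, not per decade) is a
  documented reading, not the only possible one.
- Wilcoxon/Kruskal–Wallis p-values at the 37-species scale rely on
  asymptotics the size checks only validate at their stated n.
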