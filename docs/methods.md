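# Methods

This note documents the models and procedures implemented in `nichecast`,
the assumptions behind them, the defaults and why they were chosen, and
what the synthetic test-bed does and does not establish about real data.

## Data model

Rasters are regular north-up planar grids. Cell (r, c) covers the
half-open square [x₀+c·s, x₀+(c+1)·s) × (y_top−(r+1)·s, y_top−r·s], row 0
at top, 0-based indices; a point on a shared vertical edge belongs to the
cell whose (closed) left edge it lies on, and a point on a shared
horizontal edge belongs to the lower cell. Nodata is NaN and is excluded
from every statistic. Geographic coordinate systems, datums and
reprojection are out of scope: callers must supply co-registered stacks
(`resample_nearest` is a convenience, not a GIS). Raster I/O is ESRI
ASCII grid; occurrences are plain CSV.

## Predictor screening and the spatial pre-check

The correlation screen walks predictors in their given column order and
drops one iff |Pearson r| > 0.85 against a predictor already retained
("first listed wins" — the tie rule is a design choice; the screen is
order-dependent by construction). Zero-variance columns have undefined
correlations and are retained with a warning.

Moran's *I* uses binary contiguity weights (rook or queen),
row-unstandardized, matching the classical formula
I = (n/S₀)·Σwᵢⱼ(xᵢ−x̄)(xⱼ−x̄)/Σ(xᵢ−x̄)². Inference is by value
permutation over cells (two-sided, add-one p) or the normal approximation
under randomization. On a checkerboard with rook contiguity I = −1
exactly, which the tests use as an anchor alongside an O(n²) double-loop
oracle.

## Envelope profiling and pseudo-absences

The presence envelope scores a value v on each predictor by
2·min(p, 1−p), where p is the empirical fraction of presence reference
values ≤ v with a midpoint convention for ties; values outside the
fitted [min, max] score 0, and the cell score is the minimum across
predictors. The symmetric-percentile variant is a documented choice among
the bioclim family; it is 1.0 exactly at the joint per-predictor medians.

The continuous envelope surface is discretized into five classes by exact
Jenks natural breaks (dynamic programming over the sorted unique values
with multiplicities, minimizing total within-class sum of squared
deviations; ties at a break go to the lower class). Pseudo-absences are
sampled uniformly without replacement over the cells of the three lowest
classes — cells, not vectorized polygons, which is equivalent at cell
resolution — jittered uniformly within the chosen cell, at a 1:1 ratio
with presences by default. Presence cells are excluded from the eligible
pool by default (flag to allow); sampling with replacement is available
when eligible cells are scarce.

## Boosted suitability model

Stagewise gradient boosting of depth-limited regression trees on
Bernoulli deviance. The tree internals delegate to scikit-learn's
gradient boosting; what `nichecast` adds and tests is the contract around
them: trees are added in fixed steps (default 50) while ten stratified
cross-validation folds track held-out predictive deviance, and the
ensemble size is fixed at the deviance minimum (growth stops early once
the minimum is clearly passed; if the curve is still falling at the cap,
a warning is issued and the cap used). One integer seed drives fold
assignment, bagging and the final refit, making the whole fit
reproducible.

Production defaults are the conservative occurrence-data settings —
learning rate 0.001, tree depth 5, bag fraction 0.5, cap 20,000 trees —
appropriate for a few hundred to a thousand points. The test suite and
the pipeline default raise the learning rate (0.05–0.1) and lower the cap
for its ~600-row synthetic problems; these are explicit arguments, not
changed defaults.

Evaluation reports: cross-validated AUC as the per-fold Mann-Whitney rank
statistic (ties get half credit) averaged ± SE across folds (the
aggregation is a documented choice); mean total deviance
−(2/n)Σ[y·ln ȳ + (1−y)·ln(1−ȳ)] with ȳ the prevalence — 2·ln 2 ≈ 1.386
on any balanced set; mean residual deviance with the model's predictions;
and relative influence (split-improvement totals normalized to 100).

Partial dependence overwrites one predictor with each value of a
quantile-spaced grid and averages predictions over the training rows.
Pairwise interaction strength evaluates the model on a quantile grid of
two predictors (others at training means), subtracts the best additive
main-effects fit (per-grid-level indicators), and reports residual
variance × 1000 — a relative scale on which additive responses score near
zero. Absolute interaction magnitudes are data-dependent and not
comparable across data sets.

## Extrapolation: MESS, MEDI, consensus

Per cell and variable, with f = 100 · (fraction of reference values
strictly below v): f = 0 → S = 100(v−min)/(max−min); 0 < f ≤ 50 → S = 2f;
50 < f < 100 → S = 2(100−f); f = 100 → S = 100(max−v)/(max−min). MES is
the minimum across variables; MES < 0 iff some variable is outside the
reference range. Ties count as "not below" (the strict-inequality
convention; implementations of this statistic differ and ours is
documented and oracle-tested). The reference sample is the training set
(presences plus pseudo-absences) under current conditions. A degenerate
variable (min = max) exceeded by a cell gets a large negative sentinel
with a warning.

MEDI = 100 − MES, making the index positive wherever MES < 100, so
weights 1/MEDI are well defined. The multi-GCM weighted consensus is
Proj_WA = Σ(1/MEDIᵢ)·Projᵢ / Σ(1/MEDIᵢ). By default the MEDI per GCM is a
scalar: the scenario's MEDI evaluated at the training points, summarized
by the mean (median by flag) — the summary statistic is a design choice.
A per-cell weighting mode exists since the formula is well defined
cell-wise. MEDI ≤ 0 would require MES > 100, impossible on the percent
scale, and is guarded as an error. The extrapolated-area statistic is the
percent of valid cells with MES < −20, reported to one decimal.

## Niche-overlap tests

Schoener's D normalizes each surface to sum 1 over shared valid cells and
returns 1 − ½Σ|p₁−p₂|; it is symmetric and invariant to positive
rescaling. The equivalency test pools both species' occurrences,
repartitions them at random into the original sizes, refits both models
and recomputes D (n_reps, default 100); the background test redraws one
species' points uniformly from its background region (points may share
cells — random points in a region naturally do). All tests are one-tailed
toward low overlap: divergence is supported when observed D falls below
the null's 5th percentile; p = (1 + #{null ≤ observed})/(1 + n_reps), so
p is never exactly 0. The model refitted inside replicates is pluggable
and defaults to the envelope model: refitting a boosted ensemble hundreds
of times is expensive and changes nothing about the logic of the null.

The ordination route fits principal components on the pooled background
environment, kernel-smooths occurrence and availability scores (Gaussian
KDE, Scott's rule by default) on an R×R grid (default 100) spanning the
pooled background, and computes occupancy as the availability-corrected
ratio o/e normalized to sum 1 (cells with no availability set to 0;
uncorrected mode available). Equivalency permutes occurrence labels;
similarity redraws one species' occurrences from its own background. The
geographic and environmental-space routes can disagree on real data —
they weight variables differently — and the package exposes both without
arbitrating.

Per-variable occurrence density curves use a Gaussian KDE with the normal
reference rule on an even grid spanning the predictor's layer range,
renormalized to integrate to 1 over that grid.

## Stepwise discriminant analysis

Forward entry: at each step the candidate minimizing Wilks' Lambda
(det W / det T on the trial subset) enters if its partial
F = ((n−k−s)/(k−1))·(Λ_s/Λ_{s+1} − 1) is significant at p_enter (default
0.05); the Lambda trail is strictly decreasing by construction.
Canonical variates come from the eigen-decomposition of W⁻¹B.
Classification uses linear discriminant scores with the pooled
within-class covariance and equal priors (the linear, equal-prior choice
is standard for stepwise DFA; priors are a documented assumption). No
standardization of predictors is performed. The classification matrix
reports per-class percent correct (100·diagonal/row-sum), their
unweighted mean as the "total" percent — the convention under which the
three-zone example matrix (137,15,18 / 23,297,19 / 13,32,339) gives
80.6/87.6/88.3 and a total of 85.5 — and, separately labelled, the pooled
percent (86.6 on the same counts), since the two differ whenever class
sizes do.

## Synthetic landscape generator

Layers are built by Gaussian-smoothing white noise (fixed-width kernel,
default σ = 4 cells; not a full geostatistical simulator — adequate for
the statistical structure the tests need and dependency-light), optionally
adding a north-south gradient, standardizing, and mixing the fields
through the Cholesky factor of a target correlation matrix after
orthonormalizing them over cells, so pairwise layer correlations hit
their targets essentially exactly (asserted within ±0.1). The default
six-layer stack has nominal temperature- and precipitation-like units and
moderate cross-correlations (0.4–0.6) typical of co-varying climate
layers.

Species are defined by smooth responses per predictor — scaled-logistic
monotone ramps or Gaussian bumps, combined on the logit scale — so the
true suitability of every cell is known. Presences are drawn by
acceptance sampling: uniform candidate cells accepted with probability
equal to the true suitability, jittered within the cell. The two packaged
presets ("montane", "lowland") have opposite monotone directions on two
shared predictors (temperature range, annual precipitation) and optima
placed about 1.2 landscape standard deviations into the tails, giving
restricted ranges with prevalence near 0.1 — the narrowly-distributed
regime for which envelope-based pseudo-absence profiling is designed, and
the regime in which the generating niche is recoverable (cross-validated
AUC above 0.8, opposite partial-dependence signs) from the full workflow.
Past "pseudo-GCM" scenarios are affine shifts (per-layer offset, factor,
optional offset gradient) sized so that parts of the landscape leave the
training range, exercising the MESS/MEDI machinery.

What the generator does **not** emulate: sampling bias in occurrence
records, spatially structured observation error, non-stationary
species–climate relationships, dispersal limitation and biotic
interactions (so true occupancy equals suitability here), and real
geographic projections. Passing tests therefore establish the internal
correctness and statistical calibration of the pipeline, not the
ecological validity of any particular real-world application.

## Problem sizes and numerical choices

The test suite and the acceptance script use 40–60 cell square grids,
100–300 presences per species, 1:1 pseudo-absences, 10 stratified CV
folds, 50–100 randomization replicates, and 20 seeded landscapes for the
type-I calibration of the equivalency test; oracle comparisons (MESS,
Moran's I, Jenks) run on ≤ 20×20 grids / ≤ 31 distinct values where
exhaustive enumeration is exact. Boosted fits in tests use learning rate
0.05–0.1 with caps of 300–1500 trees, sized to these problems. Numerical
conventions worth knowing: predictions are clipped to (10⁻⁹, 1−10⁻⁹)
before deviance; permutation p-values use the add-one rule; Jenks ties go
to the lower class; the envelope uses midpoint tie handling; MESS uses
strict "below" fractions; all random draws take an explicit integer seed
and no global random state is touched.

## Known limitations

- The correlation screen is order-dependent (deliberately, with "first
  listed wins"); reordering columns can change the retained set.
- The scalar-MEDI consensus weight summarizes novelty across training
  points by the mean; strongly localized novelty is better served by the
  per-cell mode.
- The equivalency/background nulls default to the envelope surrogate;
  with the boosted model the nulls are slower and can differ in spread.
- Stepwise DFA inherits the usual caveats of stepwise selection
  (entry-order instability under collinearity); collinear candidates that
  would make the within-class scatter singular are skipped at entry.
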