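# Methods

This note documents the models, statistics and design choices behind
`sdmeval`, in the order the pipeline runs them.

## Synthetic environment

Environmental layers are Gaussian random fields: white noise convolved
with an isotropic Gaussian kernel of standard deviation
`autocorr_range_cells` (default 5 cells), standardized to mean 0, sd 1.
Layers are generated independently, so pairwise correlations are small
by construction; the collinearity screen (below) is still applied, as it
would be to real predictors. The default grid is 100 × 100 cells of
1 km², i.e. a landscape of the order of a small country region. The
generator emulates the *spatial structure* of climatic predictors — it
does not emulate cross-correlated bioclimatic families, gradients with
trend, or coastlines (no nodata in the default landscape), so passing
tests demonstrate correctness of the machinery, not performance on any
particular real landscape.

## Collinearity screen

Retained predictors must satisfy |Pearson r| < 0.7 pairwise, computed
over valid cells. When a pair violates the cutoff, pairs are visited in
descending |r| and the member with the larger mean |r| against all other
retained layers is dropped — the "least correlated to others" survives.
Ties (in pair order or mean correlation) break by layer-name order, so
the result is deterministic. This tie/chain rule is our own convention;
equally defensible variants (e.g. variance-inflation-based elimination)
would retain slightly different sets.

## Virtual species

A species' true suitability is the product of per-driver Gaussian
responses `exp(−(v − opt)² / 2σ²)` (default two drivers, σ = 0.75 in
standardized units), rescaled to maximum 1 inside an optional range mask
and 0 outside. The unimodal-niche product form gives a differentiable
ground truth whose drivers are unambiguous, which is what makes
importance-recovery tests meaningful. Narrow-ranged species are
restricted to a circular sub-region with radius 0.22 × the grid's
shorter side (≈ 15% of the area); wide species use the full grid.

The default pool has 16 species with record counts log-spaced over
[6, 2094] (the two smallest fixed at 6 and 8, matching a pool with two
very data-poor species), alternating narrow and wide ranges by count
quartile so occupancy (rare/common) crosses spread (narrow/wide).
Presences are drawn without replacement with probability proportional to
suitability, so occupancy equals the record count (each record is a
distinct occupied cell). Spatial spread is the 75th percentile (linear
interpolation) of all pairwise center-to-center distances. Class
thresholds (rare ≤ 100 cells, common ≥ 130; narrow ≤ 30 km, wide
≥ 40 km, with "unclear" between) are our convention — no published
numeric cut-offs exist — and are configurable. The generator does not
model detection error, temporal structure, or spatially biased sampling
of the focal species (survey bias enters only through the target-group
background).

## Pseudo-absences and splits

The target-group background is the union of all cells occupied by any
species of the pool. Per replicate, pseudo-absences are drawn uniformly
without replacement from the background minus the focal presences,
`min(10 × n_presences, available)` of them (capped by `pa_max` if set),
resampled independently each replicate; the 10:1 ratio and per-replicate
resampling are our choices, configurable. Records are split 75/25
(train/test) independently for presences and absences, 10 replicates;
species with fewer than 10 records get one replicate per record.
Replicate seeds derive from a CRC-32 hash of
(master seed, species, algorithm, replicate) to decouple streams; the
whole experiment is bit-reproducible from (config, master seed).

## Algorithm panel

Each contract is fulfilled by a standard learner; predictions are
probabilities in [0, 1]:

- **GLM** — binomial regression on standardized linear and quadratic
  terms, forward stepwise selection by AIC (fit with a tiny ridge,
  C = 10⁴, so separable data cannot diverge).
- **GAM** — binomial regression on a 3-df Bernstein/B-spline basis per
  variable (cubic basis on the training range, first column absorbed by
  the intercept); inputs are clipped to the training range at
  prediction, preventing wild extrapolation at unsampled cells.
- **GBM** — gradient boosting (depth 3, learning rate 0.1), up to 5000
  trees, the iteration count minimizing 5-fold cross-validated log-loss.
- **RF** — random forest, 500 trees.
- **ANN** — one hidden layer, L-BFGS; weight decay ∈ {0.001, 0.01, 0.1}
  and hidden units ∈ {2, 4, 8} chosen by 5-fold CV on AUC.
- **MAXENT_LIKE** — L1-penalized logistic regression (C = 1) on an
  expanded feature set: linear always, quadratic for n ≥ 10 training
  presences, forward/reverse hinges at 4 quantile knots for n ≥ 15,
  pairwise products for n ≥ 80. This emulates maximum-entropy
  presence-background modelling with logistic output; it is an
  emulation of the modelling idea, not a reimplementation of any
  particular software.

Thresholds for binarization minimize |sensitivity − specificity| on the
training rows (candidate thresholds are midpoints between adjacent
distinct scores; ties take the lower threshold); AUC is computed on the
held-out test rows by the Mann–Whitney formulation (ties count ½).

The **consensus ensemble** pools the binarized maps of GLM, GAM, GBM, RF
and ANN across all replicates (10 × 5 = 50 maps for a data-rich species)
and votes strict majority: a cell is presence iff *more than half* the
members predict it (an exact half is absence). Its continuous score is
the vote fraction, evaluated on each replicate's test split. Because the
pooled consensus map is identical across replicates by construction,
replicate-pair map agreement is trivially maximal for the ensemble and
is therefore excluded from the similarity analysis (its rows show `na`
in the map-similarity columns of the summary).

## Map agreement at three scales

- **Cell** — Cohen's Kappa on the 2 × 2 cell-by-cell table.
- **Neighborhood** — fuzzy Kappa: `(P − E)/(1 − E)` where `P` is the
  fuzzy global matching of the pair and `E` its expectation under an
  independence null that randomly relabels both maps preserving each
  map's presence count. The null is Monte-Carlo (default 2000 seeded
  draws, batched and vectorized); at radius 0 it converges to Cohen's
  chance agreement, recovering Cohen's Kappa. A closed-form expectation
  exists for this family of statistics and would remove the Monte-Carlo
  noise; the randomization approach was chosen because it is unbiased
  under the null and directly testable.
- **Whole map** — fuzzy global matching: at each cell, the two-way
  similarity is the minimum of (a) the membership in map B's
  neighborhood of map A's category and (b) vice versa, where membership
  decays as `2^(−d/2)` out to a Euclidean radius of 4 cells (cells past
  the grid edge contribute nothing); the statistic is the mean over
  cells. It equals 1 iff the maps are identical and never falls below
  the raw agreement fraction. The 4-cell radius is the reference
  neighborhood; the exponential decay with half-distance 2 follows
  common categorical-map-comparison practice. This is the cell-based
  global fuzzy similarity; patch-decomposition variants of the statistic
  weight contiguous patches explicitly and are out of scope.

`k` replicate maps yield `k(k−1)/2` comparisons per scale (45 for 10).

## AUC ceiling under background testing

When test absences are background cells, a fraction `a` of them lies in
truly occupied cells and ties with presences, capping AUC at
`1 − a/2` for an omniscient scorer. (The ceiling evaluates to 1 at
`a = 0` and ½ at `a = 1`; a variant formula sometimes printed as
`(1 − a)/2` is inconsistent with those limits and is presumed a typo of
`1 − a/2`, which is what `theoretical_max_auc` implements.) The
acceptance suite reproduces the ceiling empirically at prevalence 0.1,
0.3 and 0.5 with the background drawn from the full landscape —
excluding sampled presences from the background would deflate its
effective prevalence and push the empirical AUC above the ceiling.

## Variable importance and DFAC

Importance of one variable for one fitted model: the mean over 5 seeded
permutations of `1 − max(0, r)`, where `r` is the Pearson correlation
between the model's predictions on the original feature table and on
the table with that single column permuted. Negative correlations are
clamped to full signal loss, keeping raw importances in [0, 1]; per run
the vector is rescaled to percentages summing to 100 (an all-zero raw
vector becomes uniform, with a warning). The permutation count is our
default; one permutation is the minimal variant and five trades little
runtime for lower variance.

DFAC (deviance from average variable contribution) is, per species ×
algorithm × variable, each replicate's |importance − replicate mean| in
percentage points; signed deviations sum to zero by construction, and a
deterministic model refitted on identical data has DFAC exactly 0. The
consensus ensemble is excluded: a combined variable contribution is not
meaningful for a majority vote over heterogeneous members.

## Mixed-model synthesis

Per response (AUC, Kappa, IFK, FGM, DFAC) the long evaluation records
are transformed — logit for AUC/FGM, Kappa-family responses first
rescaled from [−1, 1] to [0, 1], all clipped to [10⁻³, 1 − 10⁻³];
natural log of (DFAC + 10⁻³) — and fitted with a linear mixed model:
fixed effects algorithm + records + spread plus algorithm × covariate
interactions (fitted jointly; a config switch drops the interactions),
random intercept per species, REML. Covariates are z-scored internally
for numerical stability, so algorithm contrasts are evaluated at the
mean covariate values. Pairwise algorithm contrasts use the
studentized-range (Tukey) family over the k algorithm levels with
residual degrees of freedom; per-algorithm covariate slopes
(main effect + interaction) are reported with Wald p-values. A singular
or non-converging random intercept triggers a flagged
fixed-effects-only OLS fallback. The summary matrix codes each entry at
0.05/0.01/0.001 with the contrast's sign; `na` marks rows not estimable
for a response.

## Desk-scale profile and problem sizes

`pipeline.desk_scale_config()` runs the complete design — 16 species,
10 layers, 100 × 100 grid, all 6 algorithms + consensus — at sizes
chosen so the full pipeline completes in minutes on one CPU: 2
replicates for data-rich species (data-poor species keep one replicate
per record), pseudo-absences capped at 300 per replicate, GBM capped at
150 trees with 3-fold CV, a 2-point ANN grid with 2-fold CV, 30
Monte-Carlo draws for the fuzzy-Kappa null, and 2 permutations per
variable for importance. These are the package's own desk-scale sizes;
the reference configuration (`RunConfig()` defaults) keeps the full
settings. Results at desk scale are qualitative: contrast signs and the
consensus-vs-members ordering are stable across seeds, individual
p-values are not.

## Known limitations

- Virtual species have clean unimodal niches and unbiased focal
  sampling; algorithm rankings on messy real data can differ.
- The fuzzy-Kappa expectation is Monte-Carlo, so the statistic carries
  O(1/√n_null) noise; pairs of identical maps short-circuit to exactly 1.
- The consensus ensemble contributes no map-similarity or DFAC rows
  (see above), so its columns in the summary are partly `na`.
- Raster I/O supports ESRI ASCII grids (plain text); projected CRS
  handling and reprojection are out of scope — coordinates are planar
  equal-area km.
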