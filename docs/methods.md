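# Methods

This note documents the models, defaults and numerical choices behind
`traitspaces`, in the order a user meets them: the space simulator, the
occupancy measures, the space reductions, the comparison statistics, the
simulation study, and the two-group workflow. It closes with known
limitations.

## Trait-space simulation

A trait space is an `n × d` matrix of observations in `d` trait
dimensions. The simulator composes three independent ingredients:

1. **Marginals.** Each column is drawn i.i.d. from a declared family:
   `uniform(min, max)`, `normal(mean, sd)`, `lognormal(meanlog, sdlog)`,
   or `random-mix` (the family itself drawn per column from those three
   with default parameters `uniform(−0.5, 0.5)`, `normal(0, 1)`,
   `lognormal(0, 1)`). Lognormal columns are centred by subtracting the
   theoretical median `exp(meanlog)` so spaces stay roughly
   origin-centred; the position measures and the centre-referenced
   reductions take the origin as the centre of the space.
2. **Variance scheme.** Per-dimension standard-deviation multipliers
   emulate an ordination's scree without ordinating anything: `equal`
   (all 1), `multiplicative` (cumulative product of `1/d`, a geometric
   decay like a PCA eigenvalue spectrum) or `additive` (cumulative sum of
   `1/d` reversed, a linear decay like a PCoA spectrum). The bare
   cumulative product/sum prescriptions leave ordering and normalisation
   open; we produce **decreasing** multipliers renormalised so dimension
   1 has multiplier 1 — only the relative decay matters to the measures,
   all of which are (at most) homogeneous under global rescaling.
3. **Correlation.** Optional random pairwise correlations drawn uniformly
   in `[lo, hi]` (default band 0.1–0.9 in the built-in suite). A uniform
   draw of all off-diagonals is generically indefinite, so the draw is
   projected to the nearest positive-definite correlation matrix by
   alternating eigenvalue clipping (floor `1e-8`) and unit-diagonal
   rescaling. Correlation is imposed by multiplying the columns by the
   Cholesky factor **after** marginal generation; for non-normal
   marginals this linear mixing distorts the marginals slightly (a
   deliberate simplicity choice over a copula construction). The
   projection itself compresses the realised correlation band — the
   resulting mean pairwise sample correlation sits near 0.3–0.4 rather
   than the nominal 0.5 — which is acceptable because the correlated
   spaces exist to probe collinearity qualitatively.

The built-in suite holds 13 space types — uniform and normal at 3/15/50/
150 dimensions, 50-dimension correlated variants of both, a 50-dimension
random-mix space, and 50-dimension multiplicative ("PCA-like") and
additive ("PCO-like") variance spaces — each with 200 observations.
These sizes span the range found in published morphospace and functional
ecology analyses and are the defaults everywhere. Per-space seeds are
derived from one base seed via `numpy.random.SeedSequence` spawn keys
`(space_index, replicate)`, so the whole suite is reproducible from a
single integer and replicates are statistically independent.

## Occupancy measures

Definitions are in the README. Numerical choices:

* Sample variance uses the `n − 1` denominator throughout.
* The ellipsoid volume takes `λ_i` from the sample covariance matrix
  (semi-axes `√λ_i`) and is evaluated in log space
  (`log Γ` instead of `Γ`, sum of `log λ` instead of product), so the
  150-dimension spaces underflow gracefully to tiny-but-finite values
  instead of overflowing mid-computation. Any eigenvalue at or below
  `1e-12` marks the covariance as rank deficient and the volume invalid
  ("curse of multidimensionality") — this is what happens when a group
  is smaller than its dimensionality, and in the strongly compressed
  multiplicative-variance spaces.
* The MST is built with Kruskal's algorithm on the exact pairwise
  Euclidean distance matrix, with edges sorted by `(length, i, j)` so
  ties break to the lowest index pair and results are identical across
  platforms. (Tests cross-check total lengths against both exhaustive
  enumeration over all labelled spanning trees on small instances and
  scipy's independent implementation.)
* The distance metric is Euclidean; the measures assume an isotropic
  space.
* "Centre of the trait space" means the coordinate origin, both for the
  average displacement and for the centre-referenced reductions.
  Simulated spaces are origin-centred by construction; for user data
  that is not, the reductions accept `center="centroid"`.

Measures return a `MeasureValue` with a validity flag and a reason rather
than raising on degenerate input, because a study run must record an
invalid cell and continue.

## Space reductions

Each algorithm removes a fixed fraction (default 50%, configurable — the
80%/20% variants are supported through the same parameter) of the
observations, always keeping exactly `round(fraction · n)` rows
(round-half-up for platform stability):

* **random** — uniform sampling without replacement; the null model.
* **size** — rank by distance from the origin; `maximum` keeps the
  innermost points (contraction), `minimum` keeps the outermost
  (hollowing: the periphery survives, so 1-dimensional ranges are
  preserved exactly). The direction naming follows the convention that
  `minimum` hollows the space.
* **density** — sort all unordered pairs by distance; `high` accretes
  both members of each pair from the shortest pair up (a tightly packed
  subset), `low` from the longest down. Pair distances are computed once
  on the full space (single pass) rather than recomputed after each
  removal; recomputation would confound density change with size change.
* **position** — rank by distance from the single furthest point from
  the origin (ties to the lowest row index); `positive` keeps the
  points closest to that anchor, `negative` the furthest.

Rather than iteratively searching for the radius `ρ` (size, position) or
pair distance `D` (density) that yields the target fraction, the
threshold is solved directly from order statistics — the midpoint of the
two values flanking the cut (or the last consumed pair's distance for
density). The outcome is identical, deterministic, and the solved
threshold is still reported for interpretability.

## Comparison statistics

* **Scaled change scores.** For a measure on one space type,
  `scaled_i = (reduced_i − full_i) / max_j |full_j|`, paired by
  replicate, with the normaliser taken over the replicates of the same
  space type (the default strategy; an external normaliser can be
  supplied). 0 means no effect; the sign gives the direction. Invalid
  pairs are dropped and counted. With this normaliser the scores are not
  hard-bounded to [−1, 1]: a measure whose reduced value exceeds the
  baseline maximum (the covariance-ellipsoid volume can inflate
  enormously when hollowing raises every variance in many dimensions)
  legitimately exceeds 1.
* **Bhattacharyya coefficient.** `BC = Σ_b √(p_b q_b)` over shared
  equal-width bins spanning the pooled range; default bin count
  `⌈√(n_x + n_y)⌉`, exposed as a parameter because published
  implementations differ on the rule. Identical distributions give 1,
  disjoint supports 0; a zero pooled range returns 1 by convention,
  flagged degenerate.
* **Pairwise measure correlations.** Pearson on a wide (spaces ×
  measures) table with pairwise-complete handling of invalid values, so
  a measure that is undefined on some spaces (the ellipsoid volume in
  compressed-variance types) does not empty the table. Columns are
  prescaled by their maximum absolute value before standardisation so
  that values near the float underflow limit survive the variance
  computation.
* **One-way ANOVA.** Implemented from explicit sums of squares
  (`F = (SSB/df_b)/(SSW/df_w)`, p from the F distribution), tested
  against both the `SST = SSB + SSW` identity and scipy's independent
  implementation.

## The simulation study

`run_study` simulates the suite, applies all seven reduction scenarios
(1 random + size/density/position × two directions) to every space,
computes every measure on every full and reduced space, and derives four
summaries:

1. the long table of raw values;
2. the scaled change table;
3. the per-measure Bhattacharyya overlap of each scenario's scaled
   values (pooled over space types and replicates) against the random
   null — low overlap means the measure detects that kind of change;
4. the measure-by-measure Pearson correlation matrix.

For the correlation matrix the default (`correlate_on="full_per_type"`)
standardises the **full-space** values within each space type before
pooling. This choice matters: raw pooled values make every
distance-scale measure correlate near 1 because between-type magnitude
(dimension count, variance) dominates, which would say nothing about
what the measures capture. Standardising within type isolates how the
measures co-vary across replicate point configurations at fixed space
geometry. Two alternatives are built in: `"scaled"` (correlations of
the reduction change scores) and `"raw_full"` (pooled raw values).

ANOVAs report, per measure, the effect of the marginal
distribution/structure (groups = the seven 50-dimension space types) and
of dimensionality (groups = dimension counts over the uniform and normal
equal-variance series), computed on the scaled change scores pooled over
scenarios. No multiple-testing correction is applied across the ANOVA
table; the F values are descriptive.

At the default scale (13 × 20 spaces, 7 reductions each, 8 measures) a
study takes on the order of ten seconds on one CPU and is bit-for-bit
reproducible from its base seed.

## Two-group comparison

`compare_groups` bootstraps each group's rows with replacement at the
group's own size (a "full" bootstrap; an optional `sample_size` enables
rarefaction), applies each measure to every pseudo-replicate (default
500), and computes the Bhattacharyya coefficient between the two
bootstrap distributions per measure — i.e. the overlap of the measure's
sampling distributions, not a test on means. Measures invalid on more
than half the replicates of either group yield an invalid row (this is
how an `m ≤ d` group reports its undefined ellipsoid volume).

`make_empirical_fixture` builds synthetic two-group spaces shaped like
ordination output (decreasing per-dimension variance; `pca_like` =
geometric decay, `pco_like` = linear decay) with a controlled
between-group centroid shift along the first axis and optionally unequal
group sizes. It emulates the *shape* of published empirical trait
spaces for tests and demonstrations; it does not reproduce any real
dataset, and the two-group workflow is validated by parameter recovery
(a larger simulated shift must drive the position-measure overlap down).

## Known limitations

* Simulated observations are independent; real trait spaces carry
  phylogenetic or spatial correlation between rows. Passing tests on
  simulated spaces therefore says nothing about the measures' behaviour
  under non-independence.
* The covariance-ellipsoid volume is strongly sample-size dependent in
  high dimensions: `E[log det]` of a sample covariance is biased
  downward as `d/n` grows, so even *random* 50% removal shrinks the
  volume systematically (median scaled change ≈ −0.4 on 50-dimension
  normal spaces). This is a property of the statistic, not a defect of
  the reduction; volume comparisons across different sample sizes should
  use rarefaction.
* Imposing correlation by Cholesky mixing after marginal generation
  distorts non-normal marginals, and the positive-definite projection
  narrows the nominal correlation band.
* The single-pass density reduction changes nearest-neighbour density
  rather than global density; this is deliberate (to avoid confounding
  with size) but favours nearest-neighbour-type measures.
* The Bhattacharyya coefficient depends on the binning rule; results
  should quote the rule (default `⌈√(n_x + n_y)⌉` equal-width bins over
  the pooled range).
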