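# Methods

This note documents the models and procedures implemented in
`hyperdom`, the assumptions behind them, the parameters that matter, and
the choices made where the design was genuinely open.

## Data model

The raw unit is a **plot record**: stem counts per species (trees
≥ 10 cm trunk diameter), an *indeterminate* count for stems not
identified to species, an area in hectares, and optional coordinates.
Indeterminate stems contribute to every stem total (plot, dataset,
dominance denominators) but never to species totals; morphospecies
identified only to genus should be coded as indeterminate. An
**abundance table** is an ordered collection of plot records whose
species universe is exactly the species with a positive count somewhere.
Pooling column-sums the table into a **SAD** (vector of per-species
abundances plus the summed indeterminate count).

### Pre-processing conventions

* **Small-plot grouping.** Plots ≤ 0.5 ha within 1 km of each other are
  merged (summed counts, indets and area; centroid coordinates) to damp
  stochastic tree-fall noise in small areas. Distance is great-circle on
  a sphere of radius 6,371 km. "Within 1 km of each other" is read as
  *connected components* of the within-radius graph: chains merge, the
  result is order-independent, and stems and area are conserved exactly.
* **Filtering.** Analyses use plots with area strictly > 0.9 ha (small
  plots inflate per-plot species totals because species accumulate
  faster in small areas) and identification rate ≥ 80%. A grouped
  composite counts its *summed* area toward the 0.9 ha filter: grouping
  exists precisely to make several adjacent small plots behave like one
  adequate plot, so discarding composites by their member areas would
  defeat it.

## Dominance and hyperdominance

`dominance_count` sorts abundances descending and returns the smallest
k whose prefix sum reaches q·D. Greedy-by-abundance is provably minimal
(any k-subset sums to at most the top-k), and the test-suite checks
exact minimality against an exhaustive-subset oracle up to 12 species.
The denominator D defaults to *all* stems including indeterminates (the
population whose half must be covered is every tree that was counted); a
flag restricts it to identified stems. The threshold is compared with a
1e−12 relative guard so that an exactly attainable integer target (e.g.
7 of 10 stems at q = 0.7) is not missed through float overshoot.
If q·D exceeds the identified total — possible when the indeterminate
fraction exceeds 1 − q — the threshold is unreachable and an explicit
error is raised.

Hyperdominant *identities* break ties at the boundary abundance by
descending abundance, then lexicographic species name: H# itself is
tie-invariant, but reproducible identity lists require a deterministic
rule.

## Fisher's log series

The log series assigns species-abundance probability
P(n) = −xⁿ/(n·ln(1−x)), n ≥ 1, and implies S = α·ln(1 + N/α) with
x = N/(N + α). For this model the likelihood of a sample depends on the
data only through (S, N), so the maximum-likelihood α is the root of the
richness relation; `fit_fishers_alpha` brackets and solves it with Brent
iteration to 1e−12 relative tolerance (tested against R `vegan`'s
`fisher.alpha` as an independent oracle). α is fitted on identified
stems only — α is a property of the species-labelled sample. The
degenerate S = N sample (every stem its own species) has divergent α and
is returned as an explicit flag, never a number.

### Inverse-quantile expansion

To materialize a fitted model as a full SAD of richness S, the abundance
of rank r (r = 1 the most common) is the log-series quantile at
probability 1 − (r − 0.5)/S (mid-point rule; the convention is not
fixed by the method's definition, and the mid-point keeps both tails
unclipped). At regional scale (N ~ 10¹¹, x within 1e−8 of 1) generic
discrete quantile routines are unusable, so the CDF is computed as an
exact partial sum of xᵏ/k up to abundance 4,096 and, beyond, by an
Euler–Maclaurin tail sum whose integral term is the exponential integral
E₁(−n·ln x); quantiles are found by vectorized bisection. The expansion
is exact against direct summation at moderate scale (tested) and runs in
milliseconds at S = 25,000, N = 3×10¹¹. Summed abundances land within a
few percent of N (logged as a diagnostic when they stray beyond 10%);
the gap is the discretization of a continuous model into integer ranks
and shrinks with S.

## Sample-based rarefaction

For each subsample size, plots are drawn and pooled and {TS, H#, H%, α}
computed on the pool. Means come from draws *without* replacement
(within a draw, plots are distinct); standard deviations come from an
independent pass of draws *with* replacement, which makes the intervals
less conditional on the particular sample; CI = μ ± 1.96σ. Both passes
take independent RNG streams spawned from one master seed, so either is
reproducible alone. Default 200 iterations per size. A subsample with
zero identified stems (possible only at size 1 on degenerate inputs) is
redrawn with a logged warning; a subsample in which every stem is a
distinct species has divergent α and contributes NaN to the α channel
only, which nan-aware aggregation ignores.

Curves carry a mean-stems axis; `value_at_stems` reads the curve at a
common stem count by nearest mean-stems size (reporting that size as the
"equivalent plot count"), with linear interpolation as an option. The
nearest-size default reproduces the convention of reporting an
equivalent number of plots.

## Candidate hyperdominant classification

Plots are accumulated in random order until the pooled stems first reach
each rung of a stem-count ladder (default 10,000-stem increments; plots
are indivisible so rungs overshoot slightly; the dataset total is always
the final rung, where the only subsample is the full data). The
hyperdominant set is recorded at each rung over (default) 100
replicates; a species' profile is its per-rung share of replicates in
which it was hyperdominant. Groups:

1. hyperdominant in the full data and frequency ≥ 0.5 at the smallest
   rung;
2. hyperdominant in the full data, but not group 1;
3. not hyperdominant in the full data, but maximum frequency across
   rungs ≥ 0.05;
4. the rest.

The published wording behind "majority", "occasionally" and
"substantial" is qualitative, so 0.5 and 0.05 are explicit configuration
recorded in every output; group 3 uses the *maximum* across rungs
because a species that is ever substantially hyperdominant is a
plausible candidate regardless of where the peak sits. The groups
partition the species; groups 1–3 form the candidate list.

## Regional extrapolation and bias correction

Uncorrected estimates: fit α to the pooled sample, extrapolate
S_u = α·ln(1 + N/α) at the regional tree total N, expand the model at
round(S_u) ranks, and read H_u and P_u (and the full 10–90% dominance
profile) off the expanded SAD.

The correction is calibrated per configuration: `n_sims` (default 250)
log-series regions with known richness S_k ~ uniform integers on a
plausible range are expanded, sampled as j plots with conspecific
aggregation, and estimated exactly as above; ordinary least squares of
known on uncorrected gives A_k = m·A_u + c per metric (S, and H and P at
each dominance threshold — each threshold gets its own regressions).
Corrected point = m·A_u + c; 95% prediction interval
± 1.96·√(σ² + σ_R²), with σ the standard error of the predicted mean at
A_u and σ_R the residual s.d. An empirical estimate far outside the
training range triggers an extrapolation warning, not an error. A
dominance threshold whose simulated estimates never vary (H@0.1 is
identically 1 in a small community) has no identifiable slope and is
dropped from the corrected output with a warning; constant richness
estimates are a hard error.

### The aggregation model

Conspecific aggregation is parameterized by the negative-binomial
``size`` k: species i with regional abundance nᵢ has expected per-plot
count μᵢ = (nᵢ/region_area)·plot_area and per-plot variance μ + μ²/k.
Default k = 0.25 (strong clumping) — the single most consequential free
parameter, exposed in every config.

How clumping is shared across plots matters more than k itself. If each
plot's count is drawn independently, pooling j plots yields an effective
NB size of j·k (≈ 92 for 368 plots at k = 0.25) — the Poisson limit —
and the richness bias all but vanishes. Real conspecific aggregation
operates at range scale: where a species clumps, it clumps for every
plot that lands there. The default model therefore draws one gamma
intensity per species (shape k, mean μᵢ) shared by all plots, with
Poisson counts per plot given the intensity. Per-plot marginals are
exactly NB(μᵢ, k); the across-plot dependence is what lets the clumping
survive pooling. Under an Africa-shaped configuration (368 one-hectare
plots, N = 9.2×10¹⁰, richness range 2,000–10,000) this yields a mean
richness underestimate of ~35% with R² ≈ 0.99 for the known-vs-estimated
regression — a strong linear bias, readily corrected. The fully
independent variant remains available (`shared_aggregation=False`) and
is the right null model for per-plot variance checks. Species with
μᵢ below 1e−12 expected stems are treated as exact zeros (their NB mass
at zero is 1 to machine precision), which keeps regional SADs of ~25,000
species cheap to sample.

Known limitations of this machinery: aggregation is purely marginal —
no spatially explicit plot placement, distance decay, or habitat
structure — and one k applies to all species, whereas real clumping
varies by species and tends to be stronger for rarer ones.

## Synthetic data

The generator emulates exactly the structure the analysis assumes: a
log-series metacommunity of chosen (S or α, N); plot networks sampled
with the aggregation model above, scaled by per-plot area; a binomial
fraction of stems relabelled indeterminate (default 6.7%, the typical
unidentified share of large inventory compilations); uniform coordinates
in a box and configurable plot-area mixtures to exercise grouping and
filtering. Ground truth (S, H and P at every threshold) travels with
every fixture in its manifest.

It deliberately does **not** mimic floristic composition, spatial
autocorrelation of habitats, or climate covariates; synthetic plots are
exchangeable. Passing tests therefore demonstrate correctness of the
estimators under the stated generative model, not robustness to habitat
structure or non-random plot placement in real networks.

Fixture tiers: *tiny* (S = 50, 10 plots; exact oracles), *small*
(S = 1,000, N = 10⁶, 100 plots; statistical properties), and an
*Africa-shaped* simulation config (368 plots, N = 9.2×10¹⁰, S range
2,000–10,000). Conversions between tree totals and region areas use a
typical closed-canopy density of 425 stems ≥ 10 cm per hectare.
Simulation experiments in the test-suite and the acceptance script run
at 30–50 simulations per regression and 40–50 synthetic regions for
coverage — sizes at which the measured quantities (R², bias direction,
coverage) are stable to well within the asserted margins.

## Numerical notes

* Thresholds compare with a 1e−12 relative guard (see dominance); the
  α solver uses Brent with rtol 1e−12; quantile bisection is exact
  integer arithmetic on int64 bounds.
* A saturated two-point regression has no residual degrees of freedom;
  its σ_R is defined as 0.
* Rounding: S_u is rounded to the nearest integer before expansion;
  pool-scaling arithmetic rounds half away from zero.
* Determinism: every stochastic routine takes a seed or a
  `numpy.random.Generator`; rarefaction and the simulation pipeline
  spawn child streams from one master seed, so identical seeds give
  bitwise-identical results.

## Known limitations

* The prediction intervals inherit the usual OLS assumptions
  (homoscedastic residuals); at 50+ simulations the measured coverage of
  the 95% intervals is ~92–98% on synthetic regions.
* The aggregation size k is not estimable from a single pooled sample;
  conclusions about absolute regional richness scale with the assumed k,
  which is why it is surfaced in every configuration rather than fixed
  internally.
* Rarefaction is plot-based only (no individual-based or coverage-based
  variants); comparisons at a common stem count use the nearest
  mean-stems size, which can sit a few hundred stems from the requested
  target on coarse plot grids.
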