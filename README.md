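# hyperdom

Commonness and hyperdominance analysis for tropical tree inventory data.

Closed-canopy tropical forests hold tens of thousands of tree species,
yet a small minority of them account for most individual trees.
`hyperdom` quantifies that pattern from plot-inventory data — a
plot × species matrix of stem counts (trees ≥ 10 cm trunk diameter) —
for ecologists and macroecologists who need to compare commonness across
datasets and extrapolate it to whole regions.

## What it computes

Given a species-abundance distribution (SAD) — the vector of per-species
counts pooled over plots — the package provides:

* **Dominance statistics.** The minimum number of species whose summed
  abundance reaches a share *q* of all stems. At *q* = 0.5 these are the
  *hyperdominants*: their count is H#, and H% = 100·H#/TS where TS is
  total species. Unidentified ("Indet") stems count toward stem totals
  but never toward species totals.
* **Fisher's log series.** The species-abundance model with
  P(n) ∝ xⁿ/n, fitted by maximum likelihood: Fisher's α solves
  S = α·ln(1 + N/α) for an observed (S, N), with x = N/(N + α).
  An inverse-quantile expansion turns a fitted model into a full integer
  SAD at any richness — scalable to regional totals of ~10¹¹ trees.
* **Sample-based rarefaction.** Repeated subsampling of whole plots to
  put datasets of different sizes on a common footing: means of
  {TS, H#, H%, α} from subsamples drawn without replacement, confidence
  intervals μ ± 1.96σ with σ from an independent with-replacement pass.
* **Candidate hyperdominant classification.** Per-species hyperdominance
  frequency across stem-count increments of accumulated plots, and
  assignment to four commonness groups (the first three form the
  candidate hyperdominant list).
* **Bias-corrected regional extrapolation.** Plot samples of clumped
  (conspecifically aggregated) species underestimate regional richness
  when extrapolated through the log series. The package calibrates the
  bias by simulation — log-series regions of known richness S_k sampled
  with negative-binomial per-plot counts — fits A_k = m·A_u + c per
  metric, and corrects empirical estimates with 95% prediction intervals
  σ_PI = √(σ² + σ_R²).

Pre-processing utilities cover the standard inventory conventions:
grouping small plots (≤ 0.5 ha) within 1 km into composites, and
filtering to plots > 0.9 ha with ≥ 80% of stems identified to species.

## Worked example

`examples/05_regional_extrapolation.py` builds a synthetic region with
known truth, samples it with clumping, and corrects the extrapolation:

```text
sampled 100 plots, 47,300 stems from a region with S=1400, H#=61, H%=4.36%

bias regression for S over 50 simulations: slope=1.67, R^2=0.987
metric   uncorrected   corrected [95% PI]        truth
  S           845.5     1363.5 [1253.5, 1473.6]   1400.0
  H@0.5        35.0       59.4 [54.1, 64.7]   61.0
  P@0.5         4.1        4.3 [4.2, 4.5]   4.4
```

The uncorrected richness (846 species) sits ~40% below the true 1,400
because clumped sampling hides rare species; the simulation-calibrated
regression recovers the truth inside its prediction interval. The other
examples (`examples/01`–`04`) walk through dominance profiles,
log-series fitting, rarefaction, and candidate classification the same
way; each prints the numbers it computes and a line on what they mean.

A thin CLI mirrors the library for shell use:

```sh
hyperdom simulate --tier small --out fx/
hyperdom report --input fx/synthetic_counts.csv
hyperdom rarefy --input fx/synthetic_counts.csv --iterations 200 --seed 7 \
    --target-stems 20000 --output curve.csv
```

## Layout

```
src/hyperdom/       library (plot_io, sad, rarefaction, candidates,
                    extrapolation, synthetic, cli)
examples/           one narrative script per capability
tests/              pytest suite, including acceptance checks
scripts/acceptance.py
docs/methods.md     models, assumptions, parameter choices, limitations
```
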