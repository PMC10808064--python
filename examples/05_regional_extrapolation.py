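"""Bias-corrected extrapolation of a plot sample to its whole region.

Clumped (negative-binomial) plot sampling makes log-series richness
extrapolations biased low.  This example generates a region with known
truth, samples it with clumping, calibrates the bias correction by
simulation, and reports corrected estimates with 95% prediction
intervals alongside the known values.
"""

from hyperdom import (
    AggregatedSamplingConfig,
    extrapolate_region,
    generate_metacommunity,
    generate_plot_network,
    small_region_spec,
)

spec = small_region_spec(seed=21, S=1_400)
meta, known = generate_metacommunity(spec)
table = generate_plot_network(meta, spec)
print(f"sampled {table.n_plots} plots, {table.total_stems:,} stems "
      f"from a region with S={known['S']:.0f}, H#={known['H@0.5']:.0f}, "
      f"H%={known['P@0.5']:.2f}%")

config = AggregatedSamplingConfig(
    j=table.n_plots, N=spec.N, region_area=spec.region_area,
    S_range=(500, 2_000), n_sims=50, seed=9,
)
estimates, model, uncorrected = extrapolate_region(table, config)

print(f"\nbias regression for S over {config.n_sims} simulations: "
      f"slope={model.regressions['S'].slope:.2f}, "
      f"R^2={model.regressions['S'].r_squared:.3f}")
print("metric   uncorrected   corrected [95% PI]        truth")
for e in estimates:
    if e.metric in ("S", "H@0.5", "P@0.5"):
        print(f"  {e.metric:<6} {e.uncorrected:>10.1f}  {e.point:>9.1f} "
              f"[{e.pi_low:.1f}, {e.pi_high:.1f}]   {known[e.metric]:.1f}")
# The uncorrected estimates sit well below the truth; the regression
# calibrated on simulated regions pulls them back, and the prediction
# intervals should cover the known values ~95% of the time.
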