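"""Sample-based rarefaction of a synthetic plot network.

Generates a 100-plot network from a known log-series region, rarefies by
plots, and reads the curve at a common stem count, as done when
standardizing datasets of different sizes before comparing them.
"""

from hyperdom import (
    generate_metacommunity,
    generate_plot_network,
    rarefy_by_plots,
    small_region_spec,
    value_at_stems,
)

spec = small_region_spec(seed=42)  # S=1000 species, N=1e6 trees, 100 plots
meta, known = generate_metacommunity(spec)
table = generate_plot_network(meta, spec)
print(f"network: {table.n_plots} plots, {table.total_stems:,} stems "
      f"(region truth: S={known['S']:.0f}, H%={known['P@0.5']:.2f}%)")

curve = rarefy_by_plots(table, sizes=[5, 10, 25, 50, 100], iterations=200, seed=7)
print("size(plots)  mean stems   TS        H#      H%")
for i, s in enumerate(curve.sizes):
    print(f"  {s:>4d}      {curve.mean_stems[i]:>9,.0f}  "
          f"{curve.mu['TS'][i]:>7.1f}  {curve.mu['H#'][i]:>6.1f}  "
          f"{curve.mu['H%'][i]:>6.2f}")

at = value_at_stems(curve, 20_000)
print(f"\nat a common sample of ~20,000 stems (size {at.size} plots):")
for m in ("TS", "H#", "H%", "alpha"):
    print(f"  {m}: {at.mu[m]:.2f}  95% CI [{at.ci_low[m]:.2f}, {at.ci_high[m]:.2f}]")
# TS keeps climbing with effort while H# saturates, so H% declines with
# sample size — the reason datasets must be compared at a common size.
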