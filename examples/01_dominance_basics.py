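"""Dominance statistics on a small inventory table.

Builds a two-plot table in memory, pools it into a species-abundance
distribution (SAD), and reports how few species account for growing
shares of the stems.
"""

from hyperdom import AbundanceTable, PlotRecord, dominance_profile, pool_to_sad
from hyperdom.sad import dominance_count, hyperdominant_set

table = AbundanceTable(plots=(
    PlotRecord(plot_id="plot-a", area=1.0,
               counts={"Gilbertiodendron": 55, "Scorodophloeus": 20,
                       "Anonidium": 10, "Panda": 5}, indet_count=5),
    PlotRecord(plot_id="plot-b", area=1.0,
               counts={"Gilbertiodendron": 40, "Scorodophloeus": 25,
                       "Polyalthia": 8, "Panda": 2}),
))

sad = pool_to_sad(table)
h = dominance_count(sad, 0.5)
print(f"pooled stems: {sad.total_stems} ({sad.indet_count} unidentified), "
      f"species: {sad.richness}")
print(f"hyperdominants H# = {h.count}, H% = {h.percentage:.1f}% "
      f"(minimum species covering half of all stems)")
print(f"their identities: {sorted(hyperdominant_set(sad))}")
print("dominance profile (threshold -> species needed):")
for r in dominance_profile(sad):
    print(f"  {int(r.q * 100):>2d}% of stems -> {r.count} species")
# The steep profile is the classic tropical-forest pattern: a couple of
# species cover most stems while most species are rare.
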