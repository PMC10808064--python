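"""Fisher's log series: fitting and regional expansion.

Fits Fisher's alpha to a sample (S species, N identified stems), then
expands the fitted log series to a much larger tree total and measures
how hyperdominance behaves at that scale.
"""

from hyperdom import (
    dominance_count,
    expected_richness,
    fit_fishers_alpha,
    logseries_quantile_expand,
)
from hyperdom.sad import LogSeriesModel

# a sample the size of the published common-sample comparison
S_sample, N_sample = 1_132, 72_000
model = fit_fishers_alpha(S_sample, N_sample)
print(f"sample: S={S_sample}, N={N_sample} -> Fisher's alpha = {model.alpha:.1f}")

# extrapolate the fitted alpha to a regional tree total
N_region = 92e9
S_region = expected_richness(model.alpha, N_region)
print(f"expected richness at N={N_region:.0e}: {S_region:,.0f} species")

regional = logseries_quantile_expand(
    LogSeriesModel(alpha=model.alpha, N=N_region), int(round(S_region))
)
h = dominance_count(regional, 0.5)
print(f"regional-scale SAD: H# = {h.count}, H% = {h.percentage:.2f}%")
# H% shrinks from ~7% at sample scale to ~2% at regional scale: adding
# stems keeps adding rare species while the common ones only grow.
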