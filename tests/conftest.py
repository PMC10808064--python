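"""Shared fixtures: hand-built toy tables and generated synthetic tiers."""

import numpy as np
import pytest

from hyperdom import (
    AbundanceTable,
    PlotRecord,
    generate_metacommunity,
    generate_plot_network,
    small_region_spec,
    tiny_region_spec,
)


@pytest.fixture
def toy_table() -> AbundanceTable:
    """Two plots, species A=[3,0], B=[1,2], Indet=[1,0]: 7 stems total."""
    return AbundanceTable(
        plots=(
            PlotRecord(plot_id="p1", area=1.0, counts={"A": 3, "B": 1}, indet_count=1),
            PlotRecord(plot_id="p2", area=1.0, counts={"B": 2}),
        )
    )


@pytest.fixture(scope="session")
def tiny_network():
    """Tiny synthetic region (S=50, 10 plots) with its ground truth."""
    spec = tiny_region_spec(seed=7)
    meta, known = generate_metacommunity(spec)
    table = generate_plot_network(meta, spec)
    return spec, meta, known, table


@pytest.fixture(scope="session")
def small_network():
    """Small synthetic region (S=1000, 100 plots) with its ground truth."""
    spec = small_region_spec(seed=11)
    meta, known = generate_metacommunity(spec)
    table = generate_plot_network(meta, spec)
    return spec, meta, known, table


@pytest.fixture(scope="session")
def multinomial_table():
    """Plots that are i.i.d. multinomial draws from one community SAD
    (no aggregation): the closed-form rarefaction limit applies."""
    from hyperdom import fit_fishers_alpha, logseries_quantile_expand

    rng = np.random.default_rng(5)
    model = fit_fishers_alpha(200, 100_000)
    community = logseries_quantile_expand(model, 200)
    p = community.abundances / community.abundances.sum()
    plots = []
    for i in range(40):
        c = rng.multinomial(400, p)
        nz = np.flatnonzero(c)
        plots.append(
            PlotRecord(
                plot_id=f"p{i:02d}",
                area=1.0,
                counts={f"sp{j:03d}": int(c[j]) for j in nz},
            )
        )
    return AbundanceTable(plots=tuple(plots))
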