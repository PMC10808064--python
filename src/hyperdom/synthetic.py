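"""Synthetic inventory data with the statistical structure the analysis assumes.

The generator emulates, with known ground truth, the processes the
pipeline is built for: a log-series metacommunity of chosen richness (or
Fisher's alpha) and tree total; plot networks whose per-species counts
are negative-binomial with expectation equal to regional mean density
times plot area (conspecific clumping); a configurable fraction of stems
left unidentified (the ``Indet`` column); and plot areas and coordinates
that exercise the small-plot grouping and area/identification filters.

It does **not** attempt to mimic real floristic composition, spatial
autocorrelation of habitat, or climate covariates — synthetic plots are
exchangeable, so conclusions about such structure cannot be drawn from
tests built on these fixtures.

Three fixture tiers are used throughout the test-suite and examples:
``tiny`` (S ~ 50, 10 plots) for exact oracles, ``small`` (S ~ 1,000,
100 plots) for statistical properties, and an Africa-shaped
configuration (2,000-10,000 species, 368 one-hectare plots, N ~ 9.2e10)
for scaled simulation experiments.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .extrapolation import AggregatedSamplingConfig, _metric_values
from .plot_io import AbundanceTable, PlotRecord
from .sad import (
    SAD,
    LogSeriesModel,
    expected_richness,
    fit_fishers_alpha,
    logseries_quantile_expand,
)

__all__ = [
    "SyntheticRegionSpec",
    "generate_metacommunity",
    "generate_plot_network",
    "write_fixture",
    "tiny_region_spec",
    "small_region_spec",
    "africa_shaped_config",
]

#: Typical stem density of closed-canopy tropical forest (stems >= 10 cm
#: diameter per hectare) used to convert a tree total into a region area.
DEFAULT_STEM_DENSITY_PER_HA = 425.0


@dataclass(frozen=True)
class SyntheticRegionSpec:
    """Specification of a synthetic region.

    Exactly one of ``S`` and ``alpha`` must be given; the other is
    derived from the log-series richness relation at ``N``.
    """

    N: float
    region_area: float
    n_plots: int
    S: int | None = None
    alpha: float | None = None
    plot_areas: tuple[float, ...] = (1.0,)
    aggregation_size: float = 0.25
    shared_aggregation: bool = True
    indet_fraction: float = 0.067
    lat_range: tuple[float, float] = (-5.0, 5.0)
    lon_range: tuple[float, float] = (10.0, 30.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.S is None) == (self.alpha is None):
            raise ValueError("give exactly one of S and alpha")
        if not 0.0 <= self.indet_fraction < 1.0:
            raise ValueError("indet_fraction must be in [0, 1)")
        if self.n_plots < 1 or self.N <= 0 or self.region_area <= 0:
            raise ValueError("n_plots, N and region_area must be positive")

    def resolve_model(self) -> tuple[LogSeriesModel, int]:
        """(log-series model, integer richness) implied by the spec."""
        if self.S is not None:
            model = fit_fishers_alpha(self.S, self.N)
            return model, int(self.S)
        S = int(round(expected_richness(self.alpha, self.N)))
        return LogSeriesModel(alpha=float(self.alpha), N=float(self.N)), S


def generate_metacommunity(spec: SyntheticRegionSpec) -> tuple[SAD, dict[str, float]]:
    """A log-series metacommunity SAD with its ground-truth statistics.

    Richness equals the spec's (derived) S exactly; the summed abundance
    is close to N (quantile-expansion diagnostic).  The returned dict
    holds the known S plus H and P at each dominance threshold.
    """
    model, S = spec.resolve_model()
    sad = logseries_quantile_expand(model, S)
    width = len(str(S))
    labels = np.array([f"sp{i + 1:0{width}d}" for i in range(S)], dtype=object)
    sad = SAD(abundances=sad.abundances, labels=labels)
    known = _metric_values(sad, S, tuple(round(0.1 * i, 1) for i in range(1, 10)))
    return sad, known


def generate_plot_network(
    metacommunity: SAD, spec: SyntheticRegionSpec
) -> AbundanceTable:
    """Sample a plot network from a metacommunity with clumping and indets.

    Each of ``n_plots`` plots gets a uniform-random coordinate in the
    spec's box and an area drawn uniformly from ``plot_areas``.  Species
    counts are negative-binomial with mean ``(regional abundance /
    region_area) * plot area`` and ``size = aggregation_size``; with
    ``shared_aggregation`` (default) the clumping is a species-level
    gamma intensity common to all plots, so it persists across the
    network.  A binomial ``indet_fraction`` of each species' stems is
    then relabelled as indeterminate.
    """
    rng = np.random.default_rng(spec.seed)
    ab = metacommunity.abundances
    labels = (
        metacommunity.labels
        if metacommunity.labels is not None
        else np.array([f"sp{i + 1}" for i in range(ab.size)], dtype=object)
    )
    density = ab / spec.region_area  # stems per ha per species
    k = spec.aggregation_size
    shared_lam = rng.gamma(k, density / k) if spec.shared_aggregation else None

    plots = []
    for pi in range(spec.n_plots):
        area = float(rng.choice(spec.plot_areas))
        mu = density * area
        active = np.flatnonzero(mu > 1e-12)
        if shared_lam is not None:
            counts = rng.poisson(shared_lam[active] * area)
        else:
            p = k / (k + mu[active])
            counts = rng.negative_binomial(k, p)
        if spec.indet_fraction > 0:
            thinned = rng.binomial(counts, spec.indet_fraction)
        else:
            thinned = np.zeros_like(counts)
        identified = counts - thinned
        nz = np.flatnonzero(identified)
        plots.append(
            PlotRecord(
                plot_id=f"plot{pi + 1:04d}",
                area=area,
                counts={str(labels[active[i]]): int(identified[i]) for i in nz},
                indet_count=int(thinned.sum()),
                latitude=float(rng.uniform(*spec.lat_range)),
                longitude=float(rng.uniform(*spec.lon_range)),
            )
        )
    return AbundanceTable(plots=tuple(plots))


def write_fixture(
    spec: SyntheticRegionSpec, directory, stem: str = "synthetic"
) -> dict:
    """Generate and write a fixture: counts CSV, metadata CSV, manifest.

    The manifest records the spec, seed and ground truth so no test ever
    asserts against an unlabeled number.  Returns the manifest dict.
    """
    from pathlib import Path

    import pandas as pd

    from .plot_io import write_abundance_table

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta_sad, known = generate_metacommunity(spec)
    table = generate_plot_network(meta_sad, spec)
    write_abundance_table(table, directory / f"{stem}_counts.csv")
    pd.DataFrame(
        [
            {
                "plot_id": p.plot_id,
                "area_ha": p.area,
                "lat": p.latitude,
                "lon": p.longitude,
                "id_rate": p.identification_rate,
            }
            for p in table.plots
        ]
    ).to_csv(directory / f"{stem}_metadata.csv", index=False)
    manifest = {
        "spec": asdict(spec),
        "ground_truth": known,
        "files": [f"{stem}_counts.csv", f"{stem}_metadata.csv"],
    }
    with open(directory / f"{stem}_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


# ---------------------------------------------------------------------------
# Fixture tiers
# ---------------------------------------------------------------------------


def tiny_region_spec(seed: int = 0, **overrides) -> SyntheticRegionSpec:
    """S ~ 50 species, 10 one-hectare plots: for exact, enumerable oracles."""
    defaults = dict(
        N=20_000.0,
        region_area=50.0,
        n_plots=10,
        S=50,
        aggregation_size=1.0,
        indet_fraction=0.05,
        seed=seed,
    )
    defaults.update(overrides)
    return SyntheticRegionSpec(**defaults)


def small_region_spec(seed: int = 0, **overrides) -> SyntheticRegionSpec:
    """S ~ 1,000 species, 100 plots: for statistical property checks."""
    defaults = dict(
        N=1_000_000.0,
        region_area=2_500.0,
        n_plots=100,
        S=1_000,
        aggregation_size=0.25,
        indet_fraction=0.067,
        seed=seed,
    )
    defaults.update(overrides)
    return SyntheticRegionSpec(**defaults)


def africa_shaped_config(
    n_sims: int = 50, seed: int = 0, **overrides
) -> AggregatedSamplingConfig:
    """Bias-simulation configuration shaped like the African dataset.

    368 one-hectare plots, a regional total of ~9.2e10 trees, plausible
    richness 2,000-10,000 species, and strong clumping
    (``aggregation_size = 0.25``).  The region area follows from a
    typical closed-canopy stem density of ~425 stems per hectare.
    """
    N = 92e9
    defaults = dict(
        j=368,
        N=N,
        region_area=N / DEFAULT_STEM_DENSITY_PER_HA,
        S_range=(2_000, 10_000),
        plot_area=1.0,
        aggregation_size=0.25,
        n_sims=n_sims,
        seed=seed,
    )
    defaults.update(overrides)
    return AggregatedSamplingConfig(**defaults)
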