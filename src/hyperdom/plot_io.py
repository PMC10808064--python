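"""Read, validate, filter and group plot-inventory abundance tables.

The on-disk dialect mirrors common inventory deposits: a CSV with one row
per plot, a plot-identifier column, one column per species holding
non-negative integer stem counts, a reserved column (default ``Indet``)
for stems not identified to species, and optional metadata columns
(``area_ha``, ``lat``, ``lon``).  Metadata may instead live in a sidecar
CSV keyed by ``plot_id``.

Analysis-ready tables are pooled into a :class:`~hyperdom.sad.SAD` for
the statistics in :mod:`hyperdom.sad`.  Pre-processing follows standard
inventory practice: small plots (<= 0.5 ha) within 1 km of each other are
merged to damp stochastic tree-fall noise, and analyses are restricted to
plots > 0.9 ha with >= 80% of stems identified to species.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .sad import SAD

logger = logging.getLogger(__name__)

__all__ = [
    "PlotRecord",
    "AbundanceTable",
    "read_abundance_table",
    "write_abundance_table",
    "group_small_plots",
    "filter_plots",
    "pool_to_sad",
    "EARTH_RADIUS_KM",
]

#: Spherical-Earth radius used for great-circle distances.
EARTH_RADIUS_KM = 6371.0

INDET_COLUMN = "Indet"
METADATA_COLUMNS = ("area_ha", "lat", "lon")


class ValidationError(ValueError):
    """Raised when an abundance table violates its contract."""


@dataclass(frozen=True)
class PlotRecord:
    """A single inventory plot.

    ``counts`` maps species name to stems >= 10 cm diameter identified to
    that species; ``indet_count`` are stems not identified to species
    (they count toward stem totals but never toward species totals).
    """

    plot_id: str
    area: float
    counts: dict[str, int]
    indet_count: int = 0
    latitude: float | None = None
    longitude: float | None = None

    def __post_init__(self) -> None:
        if self.area <= 0:
            raise ValidationError(f"plot {self.plot_id!r}: area must be > 0")
        if self.indet_count < 0:
            raise ValidationError(f"plot {self.plot_id!r}: negative indet count")
        for sp, c in self.counts.items():
            if c < 0:
                raise ValidationError(
                    f"plot {self.plot_id!r}, species {sp!r}: negative count {c}"
                )

    @property
    def identified_stems(self) -> int:
        return int(sum(self.counts.values()))

    @property
    def total_stems(self) -> int:
        return self.identified_stems + self.indet_count

    @property
    def identification_rate(self) -> float:
        """Fraction of stems identified to species; 1.0 for an empty plot."""
        t = self.total_stems
        return self.identified_stems / t if t > 0 else 1.0

    @property
    def has_coordinates(self) -> bool:
        return self.latitude is not None and self.longitude is not None


@dataclass(frozen=True)
class AbundanceTable:
    """An ordered collection of plots with a shared species universe.

    The species universe is exactly the set of species with a positive
    count in at least one plot, in first-appearance order.
    """

    plots: tuple[PlotRecord, ...]
    species_universe: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        ids = [p.plot_id for p in self.plots]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate plot_id(s): {dupes}")
        universe: dict[str, None] = {}
        for p in self.plots:
            for sp, c in p.counts.items():
                if c > 0:
                    universe.setdefault(sp, None)
        object.__setattr__(self, "species_universe", tuple(universe))

    @property
    def n_plots(self) -> int:
        return len(self.plots)

    @property
    def total_stems(self) -> int:
        """I_p: total trees in the dataset, indeterminates included."""
        return sum(p.total_stems for p in self.plots)

    @property
    def total_area(self) -> float:
        return float(sum(p.area for p in self.plots))

    def counts_matrix(self) -> tuple[np.ndarray, np.ndarray, list[str]]:
        """Dense (plots x species) count matrix, per-plot indets, species order.

        The workhorse layout for resampling: row ``i`` is plot ``i``'s
        counts over ``species_universe``.
        """
        species = list(self.species_universe)
        idx = {sp: j for j, sp in enumerate(species)}
        mat = np.zeros((self.n_plots, len(species)), dtype=np.int64)
        indet = np.zeros(self.n_plots, dtype=np.int64)
        for i, p in enumerate(self.plots):
            indet[i] = p.indet_count
            for sp, c in p.counts.items():
                if c > 0:
                    mat[i, idx[sp]] = c
        return mat, indet, species


def read_abundance_table(
    path,
    *,
    plot_id_column: str = "plot_id",
    indet_column: str = INDET_COLUMN,
    metadata_path=None,
) -> AbundanceTable:
    """Read a plot x species CSV into a validated :class:`AbundanceTable`.

    Every column other than the plot identifier, the reserved indet
    column and recognized metadata columns (``area_ha``, ``lat``,
    ``lon``) is treated as a species.  Missing cells read as 0; species
    whose column is all-zero are dropped with a warning.  Metadata may
    come inline or from a sidecar CSV keyed by ``plot_id`` (sidecar wins).
    """
    df = pd.read_csv(path)
    if plot_id_column not in df.columns:
        raise ValidationError(f"missing plot identifier column {plot_id_column!r}")
    meta = None
    if metadata_path is not None:
        meta = pd.read_csv(metadata_path).set_index(plot_id_column)

    species_cols = [
        c
        for c in df.columns
        if c not in (plot_id_column, indet_column) and c not in METADATA_COLUMNS
    ]
    for col in species_cols + ([indet_column] if indet_column in df.columns else []):
        filled = df[col].fillna(0)
        numeric = pd.to_numeric(filled, errors="coerce")
        if numeric.isna().any():
            row = df.loc[numeric.isna(), plot_id_column].iloc[0]
            raise ValidationError(f"non-numeric count in column {col!r}, plot {row!r}")
        if (numeric < 0).any():
            row = df.loc[numeric < 0, plot_id_column].iloc[0]
            raise ValidationError(f"negative count in column {col!r}, plot {row!r}")
        df[col] = numeric.astype(np.int64)

    dead = [c for c in species_cols if df[c].sum() == 0]
    if dead:
        logger.warning("dropping %d all-zero species column(s): %s", len(dead), dead[:10])
        species_cols = [c for c in species_cols if c not in dead]

    def _meta(row, key, default=None):
        pid = row[plot_id_column]
        if meta is not None and pid in meta.index and key in meta.columns:
            v = meta.at[pid, key]
            if pd.notna(v):
                return float(v)
        if key in df.columns and pd.notna(row[key]):
            return float(row[key])
        return default

    plots = []
    for _, row in df.iterrows():
        plots.append(
            PlotRecord(
                plot_id=str(row[plot_id_column]),
                area=_meta(row, "area_ha", 1.0),
                counts={sp: int(row[sp]) for sp in species_cols if row[sp] > 0},
                indet_count=int(row[indet_column]) if indet_column in df.columns else 0,
                latitude=_meta(row, "lat"),
                longitude=_meta(row, "lon"),
            )
        )
    return AbundanceTable(plots=tuple(plots))


def write_abundance_table(
    table: AbundanceTable,
    path,
    *,
    plot_id_column: str = "plot_id",
    indet_column: str = INDET_COLUMN,
) -> None:
    """Serialize back to the deposit dialect (integer counts, bit-stable)."""
    species = list(table.species_universe)
    rows = []
    for p in table.plots:
        row: dict = {plot_id_column: p.plot_id}
        if p.latitude is not None:
            row["lat"] = p.latitude
        if p.longitude is not None:
            row["lon"] = p.longitude
        row["area_ha"] = p.area
        row[indet_column] = p.indet_count
        for sp in species:
            row[sp] = p.counts.get(sp, 0)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def _haversine_km(lat: np.ndarray, lon: np.ndarray) -> np.ndarray:
    """All-pairs great-circle distance matrix in km."""
    phi = np.radians(lat)[:, None]
    lam = np.radians(lon)[:, None]
    dphi = phi - phi.T
    dlam = lam - lam.T
    a = np.sin(dphi / 2.0) ** 2 + np.cos(phi) * np.cos(phi.T) * np.sin(dlam / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.minimum(1.0, np.sqrt(a)))


def group_small_plots(
    table: AbundanceTable,
    area_threshold: float = 0.5,
    radius_km: float = 1.0,
) -> AbundanceTable:
    """Merge small plots that lie within ``radius_km`` of each other.

    Plots with area <= ``area_threshold`` ha are partitioned into
    connected components of the graph joining pairs within the radius
    (great-circle distance), and each component is merged into a single
    composite plot with summed counts, summed indets, summed area and
    centroid coordinates.  Larger plots pass through unchanged.  Merging
    by connected components makes the result order-independent and
    handles chains of nearby plots conservatively.
    """
    small = [p for p in table.plots if p.area <= area_threshold]
    large = [p for p in table.plots if p.area > area_threshold]
    missing = [p.plot_id for p in small if not p.has_coordinates]
    if missing:
        raise ValidationError(
            f"small plots lack coordinates required for grouping: {missing}"
        )
    if not small:
        return table

    lat = np.array([p.latitude for p in small], dtype=float)
    lon = np.array([p.longitude for p in small], dtype=float)
    adj = _haversine_km(lat, lon) <= radius_km
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)

    merged: list[PlotRecord] = []
    for comp in range(n_comp):
        members = [small[i] for i in np.flatnonzero(labels == comp)]
        if len(members) == 1:
            merged.append(members[0])
            continue
        counts: dict[str, int] = {}
        for p in members:
            for sp, c in p.counts.items():
                counts[sp] = counts.get(sp, 0) + c
        merged.append(
            PlotRecord(
                plot_id="+".join(sorted(p.plot_id for p in members)),
                area=float(sum(p.area for p in members)),
                counts=counts,
                indet_count=sum(p.indet_count for p in members),
                latitude=float(np.mean([p.latitude for p in members])),
                longitude=float(np.mean([p.longitude for p in members])),
            )
        )
    logger.info(
        "grouped %d small plot(s) into %d composite(s)", len(small), len(merged)
    )
    return AbundanceTable(plots=tuple(large + merged))


def filter_plots(
    table: AbundanceTable,
    min_area: float = 0.9,
    min_id_rate: float = 0.80,
) -> AbundanceTable:
    """Keep plots with area strictly > ``min_area`` ha and identification
    rate >= ``min_id_rate``.

    Small plots inflate per-plot species totals (new species accrue
    faster in small areas), hence the strict >0.9 ha default; plots with
    fewer than 80% of stems identified to species are unreliable for
    species-level statistics.
    """
    by_area = [p for p in table.plots if p.area > min_area]
    kept = [p for p in by_area if p.identification_rate >= min_id_rate]
    logger.info(
        "filter_plots: removed %d plot(s) by area <= %g ha, %d by id rate < %g",
        table.n_plots - len(by_area),
        min_area,
        len(by_area) - len(kept),
        min_id_rate,
    )
    if not kept:
        raise ValidationError(
            f"no plots remain after filtering (min_area={min_area}, "
            f"min_id_rate={min_id_rate})"
        )
    return AbundanceTable(plots=tuple(kept))


def pool_to_sad(table: AbundanceTable) -> SAD:
    """Pool all plots into a single dataset-level SAD.

    Per-species abundances are column sums over plots; indeterminate
    stems are summed into ``indet_count`` so they contribute to stem
    totals but not species totals.
    """
    if table.n_plots == 0:
        raise ValidationError("cannot pool an empty table")
    totals: dict[str, int] = {}
    indet = 0
    for p in table.plots:
        indet += p.indet_count
        for sp, c in p.counts.items():
            if c > 0:
                totals[sp] = totals.get(sp, 0) + c
    labels = np.array(sorted(totals), dtype=object)
    ab = np.array([totals[sp] for sp in labels], dtype=np.int64)
    return SAD(abundances=ab, indet_count=indet, labels=labels)
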