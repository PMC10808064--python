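"""Per-species hyperdominance frequency and candidate classification.

Hyperdominance of the full dataset does not say *which* species would be
hyperdominant had the whole region been censused.  To assess that, plots
are randomly accumulated until the pooled stem count first reaches each
of a ladder of targets (10,000, 20,000, ... stems up to the dataset
total), the hyperdominant set is recorded at each rung, and the whole
process is repeated over many replicates.  The share of replicates in
which a species is hyperdominant at each subsample size is its
*hyperdominance frequency profile*.

Species are then assigned to four commonness groups:

1. hyperdominant in the full data and in the majority of subsamples even
   at the smallest sample size (widespread and abundant);
2. hyperdominant in the full data but only occasionally so at the
   smallest sample sizes (widespread, not always abundant);
3. not hyperdominant in the full data but hyperdominant in a substantial
   share of subsamples (locally abundant, not necessarily widespread);
4. almost never hyperdominant (neither widespread nor abundant).

Groups 1-3 form the candidate hyperdominant list.  The published wording
for "majority", "occasionally" and "substantial" is qualitative, so the
numeric thresholds are explicit configuration here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .plot_io import AbundanceTable

__all__ = [
    "SpeciesHyperdominanceProfile",
    "ClassificationResult",
    "hyperdominance_frequencies",
    "classify_candidates",
    "profiles_to_frame",
]


@dataclass
class SpeciesHyperdominanceProfile:
    """Hyperdominance frequency of one species across subsample sizes."""

    species: str
    abundance: int
    increments: np.ndarray
    frequency: np.ndarray
    full_data_hyperdominant: bool
    group: int | None = None

    def __post_init__(self) -> None:
        self.increments = np.asarray(self.increments, dtype=np.int64)
        self.frequency = np.asarray(self.frequency, dtype=float)
        if self.increments.shape != self.frequency.shape:
            raise ValueError("increments and frequency must align")
        if np.any(np.diff(self.increments) <= 0):
            raise ValueError("increments must be strictly increasing")
        if self.frequency.size and (
            self.frequency.min() < 0 or self.frequency.max() > 1
        ):
            raise ValueError("frequencies must lie in [0, 1]")


def _hyperdominant_indices(
    pooled: np.ndarray, indet: int, labels: np.ndarray, q: float
) -> np.ndarray:
    """Indices of the top-H# species of a pooled count vector.

    Ties at the boundary abundance break by descending abundance then
    lexicographic species name.
    """
    target = q * (pooled.sum() + indet) * (1.0 - 1e-12)
    order = np.lexsort((labels, -pooled))
    csum = np.cumsum(pooled[order])
    h = int(np.searchsorted(csum, target, side="left")) + 1
    return order[:h]


def hyperdominance_frequencies(
    table: AbundanceTable,
    increment: int = 10_000,
    replicates: int = 100,
    seed: int = 0,
    q: float = 0.5,
) -> list[SpeciesHyperdominanceProfile]:
    """Hyperdominance frequency of every species across subsample sizes.

    For each replicate a random plot order is drawn (without
    replacement); walking along it, the first prefix whose pooled stems
    reach each successive target of ``increment, 2*increment, ...``
    (plots are indivisible, so overshoot is allowed) yields a pooled
    subsample whose hyperdominant set is recorded.  The dataset total
    ``I_p`` is always included as the final rung, where the only possible
    subsample is the full data.

    Returns one profile per species present in the table, ordered by
    descending abundance.
    """
    if increment <= 0:
        raise ValueError("increment must be positive")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    total = table.total_stems
    if increment > total:
        raise ValueError(f"increment {increment} exceeds dataset total {total}")

    targets = np.arange(increment, total + 1, increment, dtype=np.int64)
    if targets[-1] != total:
        targets = np.append(targets, total)

    matrix, indets, species = table.counts_matrix()
    labels = np.asarray(species, dtype=object)
    stems_per_plot = matrix.sum(axis=1) + indets

    rng = np.random.default_rng(seed)
    hits = np.zeros((len(species), targets.size), dtype=np.int64)
    for _ in range(replicates):
        perm = rng.permutation(table.n_plots)
        cum_counts = np.cumsum(matrix[perm], axis=0)
        cum_indet = np.cumsum(indets[perm])
        cum_stems = np.cumsum(stems_per_plot[perm])
        cut = np.searchsorted(cum_stems, targets, side="left")
        for ti, k in enumerate(cut):
            idx = _hyperdominant_indices(
                cum_counts[k], int(cum_indet[k]), labels, q
            )
            hits[idx, ti] += 1
    freq = hits / replicates

    pooled = matrix.sum(axis=0)
    full_idx = set(
        _hyperdominant_indices(pooled, int(indets.sum()), labels, q).tolist()
    )
    order = np.lexsort((labels, -pooled))
    return [
        SpeciesHyperdominanceProfile(
            species=str(labels[i]),
            abundance=int(pooled[i]),
            increments=targets,
            frequency=freq[i],
            full_data_hyperdominant=i in full_idx,
        )
        for i in order
    ]


@dataclass(frozen=True)
class ClassificationResult:
    """Species assigned to the four commonness groups.

    ``groups`` maps group number (1-4) to species names; ``candidates``
    is the union of groups 1-3.  The thresholds used are retained so any
    output can be regenerated from its metadata.
    """

    groups: dict[int, list[str]]
    majority_threshold: float
    substantial_threshold: float

    @property
    def candidates(self) -> list[str]:
        return self.groups[1] + self.groups[2] + self.groups[3]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"species": sp, "group": g}
            for g in sorted(self.groups)
            for sp in self.groups[g]
        ]
        return pd.DataFrame(rows)


def classify_candidates(
    profiles: list[SpeciesHyperdominanceProfile],
    majority_threshold: float = 0.5,
    substantial_threshold: float = 0.05,
) -> ClassificationResult:
    """Assign each profiled species to one of the four commonness groups.

    * group 1: hyperdominant in the full data and frequency >=
      ``majority_threshold`` at the smallest increment;
    * group 2: hyperdominant in the full data but not group 1;
    * group 3: not hyperdominant in the full data, but maximum frequency
      across increments >= ``substantial_threshold``;
    * group 4: the remainder.

    The groups partition the profiled species; the candidate
    hyperdominant list is groups 1-3.  Group assignments are also written
    back onto the profiles.
    """
    groups: dict[int, list[str]] = {1: [], 2: [], 3: [], 4: []}
    for pr in profiles:
        if pr.full_data_hyperdominant:
            g = 1 if pr.frequency[0] >= majority_threshold else 2
        elif pr.frequency.max(initial=0.0) >= substantial_threshold:
            g = 3
        else:
            g = 4
        pr.group = g
        groups[g].append(pr.species)
    return ClassificationResult(
        groups=groups,
        majority_threshold=majority_threshold,
        substantial_threshold=substantial_threshold,
    )


def profiles_to_frame(profiles: list[SpeciesHyperdominanceProfile]) -> pd.DataFrame:
    """Frequency matrix: one row per species (ranked by abundance),
    one column per subsample stem count, entries in [0, 1]."""
    if not profiles:
        return pd.DataFrame()
    cols = [int(t) for t in profiles[0].increments]
    data = {
        "species": [p.species for p in profiles],
        "abundance": [p.abundance for p in profiles],
        "full_data_hyperdominant": [p.full_data_hyperdominant for p in profiles],
    }
    frame = pd.DataFrame(data)
    freq = pd.DataFrame(
        np.vstack([p.frequency for p in profiles]), columns=[str(c) for c in cols]
    )
    return pd.concat([frame, freq], axis=1)
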