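"""Sample-based rarefaction over plots, with a dual resampling scheme.

Diversity statistics from inventory datasets depend strongly on sample
size, so datasets are compared after rarefying: for each subsample size
(number of plots), plots are repeatedly drawn, their stems pooled and the
statistics of interest — total species TS, number of hyperdominants H#,
hyperdominant percentage H% and Fisher's alpha — computed on the pooled
sample.

Means are taken over draws *without* replacement within a subsample;
standard deviations come from an independent pass of draws *with*
replacement, which decouples the confidence intervals from the particular
sample in hand.  Confidence intervals are ``mu +/- 1.96 * sigma``.
Curves are indexed by plot count but carry a mean-stems axis so datasets
of differing plot sizes can be compared at a common stem count.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .plot_io import AbundanceTable
from .sad import fit_fishers_alpha

logger = logging.getLogger(__name__)

__all__ = ["RarefactionCurve", "MetricAtStems", "rarefy_by_plots", "value_at_stems", "METRICS"]

METRICS = ("TS", "H#", "H%", "alpha")

Z_95 = 1.96


def _pooled_metrics(pooled: np.ndarray, indet: int, q: float) -> tuple[float, float, float, float]:
    """(TS, H#, H%, alpha) of a pooled count vector plus indet stems."""
    nz = pooled[pooled > 0]
    ts = nz.size
    if ts == 0:
        raise ValueError("no identified stems in subsample")
    n_id = int(nz.sum())
    target = q * (n_id + indet) * (1.0 - 1e-12)
    csum = np.cumsum(np.sort(nz)[::-1])
    h = int(np.searchsorted(csum, target, side="left")) + 1
    if ts == n_id:  # all singletons: ML alpha diverges
        alpha = math.nan
    else:
        alpha = fit_fishers_alpha(ts, n_id).alpha
    return float(ts), float(h), 100.0 * h / ts, alpha


@dataclass(frozen=True)
class RarefactionCurve:
    """Per-size means, s.d. and CIs of the four diversity metrics.

    ``mu[m][i]`` is the mean of metric ``m`` at ``sizes[i]`` plots over
    the without-replacement draws; ``sigma`` comes from the
    with-replacement pass; CI bounds are ``mu +/- 1.96 sigma`` exactly.
    """

    sizes: np.ndarray
    mean_stems: np.ndarray
    mu: dict[str, np.ndarray]
    sigma: dict[str, np.ndarray]
    iterations: int
    seed: int

    def ci_low(self, metric: str) -> np.ndarray:
        return self.mu[metric] - Z_95 * self.sigma[metric]

    def ci_high(self, metric: str) -> np.ndarray:
        return self.mu[metric] + Z_95 * self.sigma[metric]

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: size, mean_stems, metric, mu, sigma, ci bounds."""
        rows = []
        for m in self.mu:
            for i, s in enumerate(self.sizes):
                rows.append(
                    {
                        "size": int(s),
                        "mean_stems": self.mean_stems[i],
                        "metric": m,
                        "mu": self.mu[m][i],
                        "sigma": self.sigma[m][i],
                        "ci_low": self.mu[m][i] - Z_95 * self.sigma[m][i],
                        "ci_high": self.mu[m][i] + Z_95 * self.sigma[m][i],
                    }
                )
        return pd.DataFrame(rows)


def _metric_pass(
    matrix: np.ndarray,
    indets: np.ndarray,
    sizes: np.ndarray,
    iterations: int,
    rng: np.random.Generator,
    replace: bool,
    q: float,
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """One resampling pass; returns per-metric (n_sizes, iterations) draws
    and the per-size mean pooled stem count."""
    n_plots = matrix.shape[0]
    vals = {m: np.empty((sizes.size, iterations)) for m in METRICS}
    stems = np.empty((sizes.size, iterations))
    for si, size in enumerate(sizes):
        for it in range(iterations):
            for _attempt in range(100):
                idx = rng.choice(n_plots, size=int(size), replace=replace)
                pooled = matrix[idx].sum(axis=0)
                ind = int(indets[idx].sum())
                if pooled.sum() > 0:
                    break
                logger.warning("redrawing subsample with zero identified stems")
            ts, h, hp, alpha = _pooled_metrics(pooled, ind, q)
            vals["TS"][si, it] = ts
            vals["H#"][si, it] = h
            vals["H%"][si, it] = hp
            vals["alpha"][si, it] = alpha
            stems[si, it] = pooled.sum() + ind
    return vals, stems.mean(axis=1)


def rarefy_by_plots(
    table: AbundanceTable,
    sizes: Sequence[int] | None = None,
    iterations: int = 200,
    seed: int = 0,
    q: float = 0.5,
) -> RarefactionCurve:
    """Rarefaction curve of TS, H#, H% and Fisher's alpha by plot count.

    Parameters
    ----------
    table
        The (already filtered/grouped) abundance table.
    sizes
        Subsample sizes in plots; defaults to ``1..n_plots``.
    iterations
        Draws per size in each pass (default 200).
    seed
        Master seed; two independent child streams drive the means pass
        (without replacement) and the s.d. pass (with replacement), so
        either pass is reproducible alone.
    q
        Stem-share threshold defining hyperdominance (default 0.5).
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    if sizes is None:
        sizes = np.arange(1, table.n_plots + 1)
    sizes = np.asarray(sizes, dtype=np.int64)
    if sizes.size == 0 or sizes.min() < 1 or sizes.max() > table.n_plots:
        raise ValueError(f"sizes must lie in [1, {table.n_plots}]")

    matrix, indets, _ = table.counts_matrix()
    ss = np.random.SeedSequence(seed)
    seq_mean, seq_ci = ss.spawn(2)
    vals_mu, mean_stems = _metric_pass(
        matrix, indets, sizes, iterations, np.random.default_rng(seq_mean), False, q
    )
    vals_sd, _ = _metric_pass(
        matrix, indets, sizes, iterations, np.random.default_rng(seq_ci), True, q
    )

    mu = {m: np.nanmean(vals_mu[m], axis=1) for m in METRICS}
    if iterations > 1:
        sigma = {m: np.nanstd(vals_sd[m], axis=1, ddof=1) for m in METRICS}
    else:
        sigma = {m: np.zeros(sizes.size) for m in METRICS}
    return RarefactionCurve(
        sizes=sizes,
        mean_stems=mean_stems,
        mu=mu,
        sigma=sigma,
        iterations=iterations,
        seed=seed,
    )


@dataclass(frozen=True)
class MetricAtStems:
    """Curve values read off at a common stem count."""

    size: int
    mean_stems: float
    mu: dict[str, float]
    ci_low: dict[str, float]
    ci_high: dict[str, float]


def value_at_stems(
    curve: RarefactionCurve,
    target_stems: float,
    method: Literal["nearest", "interpolate"] = "nearest",
) -> MetricAtStems:
    """Read the curve at a target pooled stem count.

    ``nearest`` (default) selects the subsample size whose mean stem
    count is closest to the target and reports that size as the
    "equivalent plot count"; ``interpolate`` linearly interpolates each
    metric on the mean-stems axis (the reported size is still the
    nearest one).
    """
    ms = curve.mean_stems
    if not (ms.min() <= target_stems <= ms.max()):
        raise ValueError(
            f"target {target_stems} outside achievable range "
            f"[{ms.min():.1f}, {ms.max():.1f}] stems"
        )
    i = int(np.argmin(np.abs(ms - target_stems)))
    if method == "nearest":
        mu = {m: float(curve.mu[m][i]) for m in curve.mu}
        lo = {m: float(curve.ci_low(m)[i]) for m in curve.mu}
        hi = {m: float(curve.ci_high(m)[i]) for m in curve.mu}
    elif method == "interpolate":
        mu = {m: float(np.interp(target_stems, ms, curve.mu[m])) for m in curve.mu}
        lo = {m: float(np.interp(target_stems, ms, curve.ci_low(m))) for m in curve.mu}
        hi = {m: float(np.interp(target_stems, ms, curve.ci_high(m))) for m in curve.mu}
    else:
        raise ValueError(f"unknown method {method!r}")
    return MetricAtStems(
        size=int(curve.sizes[i]),
        mean_stems=float(ms[i]),
        mu=mu,
        ci_low=lo,
        ci_high=hi,
    )
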