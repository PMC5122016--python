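"""Detection-sensitivity statistics under the dilution model.

The number of molecules of a gene in a diluted replicate is Poisson with
mean equal to the gene's expected molecule count; presence (at least one
molecule) is therefore Bernoulli with probability 1 - exp(-lambda), and
the number of genes present follows a Poisson-Binomial distribution.
Observed/expected detection ratios get Byar's approximation to the exact
Poisson interval, and sequencing-depth effects are probed by in-silico
downsampling of assigned reads.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PresenceModel",
    "DetectedGeneDistribution",
    "presence_probability",
    "detected_gene_distribution",
    "byars_ratio_ci",
    "downsample_counts",
    "detect",
]


@dataclass
class PresenceModel:
    """Per-gene expected molecule counts and presence probabilities."""

    expected_molecules: np.ndarray
    presence_probability: np.ndarray

    @classmethod
    def from_expected_molecules(cls, lam) -> "PresenceModel":
        lam = np.asarray(lam, dtype=float)
        return cls(lam, presence_probability(lam))


@dataclass
class DetectedGeneDistribution:
    """Exact Poisson-Binomial distribution of the number of genes present
    (or detected) in a replicate."""

    support: np.ndarray
    pmf: np.ndarray
    mean: float
    ci_low: int
    ci_high: int

    @property
    def variance(self) -> float:
        return float(((self.support - self.mean) ** 2 * self.pmf).sum())


def presence_probability(lam):
    """P(at least one molecule in the tube) = 1 - exp(-lambda)."""
    lam = np.asarray(lam, dtype=float)
    if np.any(lam < 0):
        raise ValueError("expected molecule count must be non-negative")
    out = -np.expm1(-lam)
    return float(out) if out.ndim == 0 else out


def detected_gene_distribution(p, level: float = 0.95) -> DetectedGeneDistribution:
    """Exact Poisson-Binomial pmf of the number of successes among
    independent Bernoulli trials with probabilities ``p``.

    Computed by iterative convolution (numerically stable, exact to
    floating point); the interval is the equal-tailed [2.5, 97.5]%
    quantile pair of the CDF.
    """
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    pmf = np.zeros(p.size + 1)
    pmf[0] = 1.0
    hi = 0  # highest index with nonzero mass, bounds the convolution
    for pi in p:
        if pi == 0.0:
            continue
        sl = pmf[: hi + 2].copy()
        sl[1 : hi + 2] = sl[1 : hi + 2] * (1 - pi) + pmf[: hi + 1] * pi
        sl[0] *= 1 - pi
        pmf[: hi + 2] = sl
        hi += 1
    cdf = np.cumsum(pmf)
    alpha = (1 - level) / 2
    lo = int(np.searchsorted(cdf, alpha))
    up = int(np.searchsorted(cdf, 1 - alpha))
    return DetectedGeneDistribution(
        support=np.arange(p.size + 1),
        pmf=pmf,
        mean=float(p.sum()),
        ci_low=lo,
        ci_high=up,
    )


def _byar_poisson_ci(observed: int, level: float) -> tuple[float, float]:
    # Cube-root (Byar) approximation to the exact Poisson interval.
    z = stats.norm.ppf(1 - (1 - level) / 2)
    if observed > 0:
        lower = observed * (1 - 1 / (9 * observed) - z / (3 * np.sqrt(observed))) ** 3
    else:
        lower = 0.0
    op = observed + 1
    upper = op * (1 - 1 / (9 * op) + z / (3 * np.sqrt(op))) ** 3
    return lower, upper


def byars_ratio_ci(
    observed_count: int, expected_count: float, level: float = 0.95
) -> tuple[float, float]:
    """Byar's approximate CI for an observed/expected Poisson count ratio."""
    if observed_count < 0 or observed_count != int(observed_count):
        raise ValueError("observed count must be a non-negative integer")
    if expected_count <= 0:
        raise ValueError("expected count must be positive")
    lo, hi = _byar_poisson_ci(int(observed_count), level)
    return lo / expected_count, hi / expected_count


def downsample_counts(counts, n_reads: int = 500_000, seed=None) -> np.ndarray:
    """Subsample ``n_reads`` reads without replacement from a count vector
    (multivariate hypergeometric draw over read identities)."""
    counts = np.asarray(counts)
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    total = int(counts.sum())
    if total < n_reads:
        raise ValueError(
            f"insufficient depth: {total} reads available, {n_reads} requested"
        )
    rng = np.random.default_rng(seed)
    return rng.multivariate_hypergeometric(counts.astype(np.int64), n_reads)


def detect(
    count_matrix: pd.DataFrame, bulk_frequency=None
) -> tuple[pd.DataFrame, pd.Series]:
    """Detection matrix (count >= 1) and per-sample detected-gene counts.

    If ``bulk_frequency`` (aligned with the matrix rows) is given, genes
    absent from the bulk (frequency 0) are excluded before counting.
    """
    counts = count_matrix
    if bulk_frequency is not None:
        freq = np.asarray(bulk_frequency, dtype=float)
        counts = counts.loc[freq > 0]
    detected = counts >= 1
    return detected, detected.sum(axis=0)
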