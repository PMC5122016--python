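"""Read-coverage uniformity along gene bodies and genomic region assignment.

Per-nucleotide coverage vectors (transcript space, 5'->3') are normalized
so a uniform read distribution scores 1 at every position.  Because the
poly-T-primed protocols anchor cDNA synthesis at the 3' end, positional
aggregation aligns genes at their 3' terminus.  Uniformity is summarized
with a Kolmogorov-Smirnov statistic against the uniform positional
distribution, and relative profiles use 100 equal bins from 5' to 3'.
Reads are also assigned hierarchically to genomic region categories
(rRNA exon > rRNA repeat > exon > intron > flank > intergenic).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .gene_traits import merge_intervals

__all__ = [
    "REGION_PRIORITY",
    "normalize_per_nucleotide",
    "aggregate_absolute_3prime",
    "ks_uniformity",
    "binned_relative_coverage",
    "expression_stratified_profiles",
    "assign_genomic_regions",
    "read_coverage_tsv",
]

REGION_PRIORITY = (
    "rRNA_exon", "rRNA_repeat", "exon", "intron", "flank", "intergenic",
)
DEFAULT_FLANK = 5000


def normalize_per_nucleotide(coverage) -> np.ndarray:
    """Scale so the positional mean is exactly 1 (uniform coverage -> all
    ones)."""
    cov = np.asarray(coverage, dtype=float)
    total = cov.sum()
    if total <= 0:
        raise ValueError("coverage is all zero")
    return cov * cov.size / total


def aggregate_absolute_3prime(
    coverages: list[np.ndarray],
    min_mean_cov: float = 2.0,
    min_obs: int = 25,
) -> pd.DataFrame:
    """Observed/expected coverage as a function of absolute distance from
    the 3' end.

    Each gene x sample coverage vector is one observation.  Observations
    with mean per-base coverage below ``min_mean_cov`` are dropped; each
    retained vector is normalized to positional mean 1 and aligned at the
    3' end (position 0 = 3'-terminal base).  At each position the expected
    value is the number of contributing observations and the observed
    value the sum of normalized coverages; positions with fewer than
    ``min_obs`` observations are dropped.
    """
    kept = [
        normalize_per_nucleotide(c)[::-1]
        for c in coverages
        if np.asarray(c, dtype=float).mean() >= min_mean_cov
    ]
    if not kept:
        warnings.warn("no observation passes the coverage filter")
        return pd.DataFrame(columns=["position", "observed", "expected", "ratio"])
    max_len = max(len(c) for c in kept)
    obs = np.zeros(max_len)
    n = np.zeros(max_len, dtype=int)
    for c in kept:
        obs[: len(c)] += c
        n[: len(c)] += 1
    ok = n >= min_obs
    return pd.DataFrame(
        {
            "position": np.arange(max_len)[ok],
            "observed": obs[ok],
            "expected": n[ok].astype(float),
            "ratio": obs[ok] / n[ok],
        }
    )


def ks_uniformity(normalized_coverage, mode: str = "positional") -> tuple[float, float]:
    """KS distance of the coverage mass distribution from uniform.

    ``positional`` (default) treats read mass as a sample over positions:
    the empirical CDF is the cumulative fraction of mass from 5' to 3',
    compared against the uniform diagonal.  ``value`` instead tests the
    distribution of normalized per-base values against Uniform(0, 2).
    """
    cov = np.asarray(normalized_coverage, dtype=float)
    if cov.size == 0:
        raise ValueError("empty coverage")
    if mode == "positional":
        # Discrete-vs-discrete comparison on the shared positional support:
        # sup over positions of |cumulative mass - cumulative uniform|.
        mass = cov / cov.sum()
        ecdf = np.cumsum(mass)
        uniform = np.arange(1, cov.size + 1) / cov.size
        d = float(np.abs(ecdf - uniform).max())
        # Effective sample size = total mass in reads is unknown after
        # normalization; use the number of positions for the p-value scale.
        p = float(stats.kstwo.sf(d, cov.size))
        return d, p
    if mode == "value":
        res = stats.kstest(cov, stats.uniform(loc=0, scale=2).cdf)
        return float(res.statistic), float(res.pvalue)
    raise ValueError(f"unknown mode {mode!r}")


def binned_relative_coverage(coverage, n_bins: int = 100) -> np.ndarray | None:
    """Average per-nucleotide coverage in ``n_bins`` equal 5'->3' bins,
    normalized to sum to 1.  Bin sizes differ by at most one base, with
    the remainder spread over the leading bins."""
    cov = np.asarray(coverage, dtype=float)
    if cov.size < n_bins:
        warnings.warn(f"transcript shorter than {n_bins} bins; skipped")
        return None
    edges = np.round(np.linspace(0, cov.size, n_bins + 1)).astype(int)
    means = np.array([cov[a:b].mean() for a, b in zip(edges[:-1], edges[1:])])
    total = means.sum()
    if total <= 0:
        raise ValueError("coverage is all zero")
    return means / total


def expression_stratified_profiles(
    coverages: list[np.ndarray],
    strata_breaks: list[float],
    n_bins: int = 100,
) -> dict[str, np.ndarray]:
    """Mean binned profile per expression stratum.

    Strata are defined by average per-base coverage cut points
    (``strata_breaks`` ascending); each gene x sample observation joins
    the stratum its average coverage falls in.  Each returned profile
    sums to 1.
    """
    edges = [0.0, *strata_breaks, np.inf]
    labels = [f"[{a:g},{b:g})" for a, b in zip(edges[:-1], edges[1:])]
    buckets: dict[str, list[np.ndarray]] = {lab: [] for lab in labels}
    for cov in coverages:
        cov = np.asarray(cov, dtype=float)
        prof = binned_relative_coverage(cov, n_bins)
        if prof is None:
            continue
        mean_cov = cov.mean()
        for lab, a, b in zip(labels, edges[:-1], edges[1:]):
            if a <= mean_cov < b:
                buckets[lab].append(prof)
                break
    out = {}
    for lab, profs in buckets.items():
        if not profs:
            warnings.warn(f"empty expression stratum {lab}")
            continue
        mean_prof = np.mean(profs, axis=0)
        out[lab] = mean_prof / mean_prof.sum()
    return out


@dataclass
class RegionAnnotationSet:
    """Merged half-open interval sets per region category, queried in
    fixed priority order."""

    regions: dict[str, list[tuple[int, int]]]
    flank_width: int = DEFAULT_FLANK

    def __post_init__(self) -> None:
        self.regions = {k: merge_intervals(v) for k, v in self.regions.items()}

    @classmethod
    def from_gene_annotation(
        cls,
        exons: list[tuple[int, int]],
        gene_spans: list[tuple[int, int]],
        rrna_exons: list[tuple[int, int]] = (),
        rrna_repeats: list[tuple[int, int]] = (),
        flank_width: int = DEFAULT_FLANK,
    ) -> "RegionAnnotationSet":
        introns = []
        for gs, ge in merge_intervals(gene_spans):
            covered = merge_intervals([iv for iv in exons if iv[0] < ge and iv[1] > gs])
            pos = gs
            for es, ee in covered:
                if es > pos:
                    introns.append((pos, min(es, ge)))
                pos = max(pos, ee)
            if pos < ge:
                introns.append((pos, ge))
        flanks = [
            iv
            for gs, ge in merge_intervals(gene_spans)
            for iv in ((max(0, gs - flank_width), gs), (ge, ge + flank_width))
        ]
        return cls(
            regions={
                "rRNA_exon": list(rrna_exons),
                "rRNA_repeat": list(rrna_repeats),
                "exon": list(exons),
                "intron": introns,
                "flank": flanks,
            },
            flank_width=flank_width,
        )


def _overlaps(iv: tuple[int, int], merged: list[tuple[int, int]]) -> bool:
    s, e = iv
    for ms, me in merged:
        if ms >= e:
            return False
        if me > s:
            return True
    return False


def assign_genomic_regions(
    read_intervals: list[tuple[int, int]], regions: RegionAnnotationSet
) -> pd.Series:
    """Greedy hierarchical read assignment: each read goes to the first
    category in :data:`REGION_PRIORITY` it overlaps; anything left is
    intergenic.  Counts partition the reads."""
    counts = {cat: 0 for cat in REGION_PRIORITY}
    for i, iv in enumerate(read_intervals):
        if not (isinstance(iv, tuple) and len(iv) == 2 and iv[1] > iv[0]):
            raise ValueError(f"malformed read interval at line {i + 1}: {iv!r}")
        for cat in REGION_PRIORITY[:-1]:
            if _overlaps(iv, regions.regions.get(cat, [])):
                counts[cat] += 1
                break
        else:
            counts["intergenic"] += 1
    return pd.Series(counts)


def read_coverage_tsv(path) -> pd.DataFrame:
    """Read a per-transcript coverage table (gene_id, sample_id,
    comma-separated per-base depths)."""
    frame = pd.read_csv(path, sep="\t")
    frame["coverage"] = frame["coverage"].map(
        lambda s: np.fromstring(str(s), sep=",", dtype=float)
    )
    return frame
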