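"""Biophysical and bioinformatic gene covariates.

Covariates used throughout the benchmark: transcript length L (kb), GC
fraction G, presence of an internal A-hexamer A (a run of >= 6 adenosines,
a poly-T mispriming liability), mean local secondary-structure strength S
(kcal/mol, averaged over 100-nt sliding windows), plus two ambiguity
metrics over each gene's exon union — the fraction of 50-bp windows that
are uniquely alignable and the fraction of bases overlapped by another
gene annotation on either strand.  Genes with a fully mappable,
non-overlapping exon union are "computationally unambiguous".

Coordinates are 0-based, half-open (BED convention) throughout.
"""

from __future__ import annotations

import re
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "gc_content",
    "has_internal_a_hexamer",
    "windowed_structure_score",
    "weighted_gene_trait",
    "ambiguity_metrics",
    "filter_gene_universe",
    "pairing_heuristic_energy",
    "merge_intervals",
]

_A_HEXAMER = re.compile(r"A{6,}", re.IGNORECASE)


def gc_content(sequence: str) -> float:
    """GC fraction over non-N bases, case-insensitive; U treated as T."""
    seq = sequence.upper()
    n_informative = sum(1 for b in seq if b != "N")
    if n_informative == 0:
        raise ValueError("sequence is empty or all-N")
    gc = seq.count("G") + seq.count("C")
    return gc / n_informative


def has_internal_a_hexamer(sequence: str) -> bool:
    """True iff the sequence contains >= 6 consecutive adenosines."""
    if not sequence:
        raise ValueError("empty sequence")
    return _A_HEXAMER.search(sequence) is not None


def pairing_heuristic_energy(window: str) -> float:
    """Crude, non-physical stand-in for a folding energy: the negative of
    a weighted base-pairing content (G/C weighted 3, A/U 2), per the
    nearest-neighbour intuition that GC-rich windows fold more stably.
    Use a real thermodynamic engine for physical values."""
    seq = window.upper()
    n = len(seq)
    if n == 0:
        return 0.0
    gc = (seq.count("G") + seq.count("C")) / n
    au = (seq.count("A") + seq.count("T") + seq.count("U")) / n
    return -10.0 * (3.0 * gc + 2.0 * au) / 3.0


def windowed_structure_score(
    sequence: str,
    window: int = 100,
    step: int = 1,
    energy_fn: Callable[[str], float] = pairing_heuristic_energy,
) -> float:
    """Mean of ``energy_fn`` over sliding windows along the sequence.

    Sequences shorter than the window get a single whole-sequence window.
    """
    n = len(sequence)
    if n == 0:
        raise ValueError("empty sequence")
    if n < window:
        starts: Iterable[int] = (0,)
        window = n
    else:
        starts = range(0, n - window + 1, step)
    scores = []
    for i in starts:
        try:
            scores.append(energy_fn(sequence[i : i + window]))
        except Exception as exc:  # surface which window failed
            raise RuntimeError(f"energy function failed at window {i}") from exc
    return float(np.mean(scores))


def weighted_gene_trait(isoform_values, isoform_weights) -> float:
    """Expression-weighted average of an isoform-level trait."""
    v = np.asarray(isoform_values, dtype=float)
    w = np.asarray(isoform_weights, dtype=float)
    if v.shape != w.shape:
        raise ValueError("values and weights must be conformable")
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    tot = w.sum()
    if tot <= 0:
        raise ValueError("weights must not all be zero")
    return float((v * w).sum() / tot)


def merge_intervals(intervals: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge half-open intervals into a disjoint sorted union."""
    ivs = sorted((s, e) for s, e in intervals if e > s)
    merged: list[tuple[int, int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def _intersect_length(a: list[tuple[int, int]], b: list[tuple[int, int]]) -> int:
    total = 0
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if e > s:
            total += e - s
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return total


def ambiguity_metrics(
    gene_exon_union: Sequence[tuple[int, int]],
    mappability_windows: Sequence[tuple[int, int]],
    other_annotations: Sequence[tuple[int, int]],
    window: int = 50,
) -> tuple[float, float]:
    """(mappability_fraction, overlap_fraction) over a gene's exon union.

    Mappability is the fraction of ``window``-bp windows starting inside
    the exon union whose full extent lies within a uniquely-alignable
    region; overlap is the base fraction of the exon union intersecting
    any other gene's exons on either strand.
    """
    union = merge_intervals(gene_exon_union)
    if not union:
        raise ValueError("empty exon union")
    union_len = sum(e - s for s, e in union)
    mappable = merge_intervals(mappability_windows)
    others = merge_intervals(other_annotations)

    n_windows = 0
    n_unique = 0
    for s, e in union:
        for start in range(s, e):
            n_windows += 1
            w = (start, start + window)
            if any(ms <= w[0] and w[1] <= me for ms, me in mappable):
                n_unique += 1
    mappability_fraction = n_unique / n_windows if n_windows else 0.0
    overlap_fraction = _intersect_length(union, others) / union_len
    return mappability_fraction, overlap_fraction


def filter_gene_universe(annotations: pd.DataFrame, min_isoform_nt: int = 300) -> pd.DataFrame:
    """Apply the analysis-universe filters and flag unambiguous genes.

    Expects columns: gene_id, gene_type, min_isoform_length, chromosome,
    and (optionally) overlap_fraction and mappability_fraction.  Excludes
    ribosomal genes, genes with any isoform shorter than
    ``min_isoform_nt``, and mitochondrial genes; flags the unambiguous
    subset (overlap 0, mappability 1) when the metrics are present.
    """
    ann = annotations.copy()
    keep = (
        (~ann["gene_type"].str.contains("rRNA", case=False, na=False))
        & (ann["min_isoform_length"] >= min_isoform_nt)
        & (~ann["chromosome"].isin(["chrM", "MT", "M"]))
    )
    universe = ann.loc[keep].copy()
    if {"overlap_fraction", "mappability_fraction"} <= set(universe.columns):
        universe["computationally_unambiguous"] = (
            (universe["overlap_fraction"] == 0.0)
            & (universe["mappability_fraction"] == 1.0)
        )
    return universe
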