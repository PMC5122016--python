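"""Accuracy against the bulk reference: size-factor normalization, fold
deviation, accuracy classes/outliers, and transfer-function summaries.

Raw counts are depth-normalized with median-of-ratios size factors; the
bulk relative frequencies, treated as truth, join the size-factor
computation as a pseudo-sample so they land on the same scale.  A gene's
fold deviation is its normalized count divided by its bulk-scaled
expectation (>1 = overestimated).  Per-method 5% tails of the median
fold deviation are over/underestimated classes, the 1% tails outliers,
union-merged across input amounts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .precision_analysis import trait_enrichment

__all__ = [
    "SizeFactorSet",
    "size_factors",
    "scale_reference",
    "fold_deviation",
    "classify_accuracy",
    "transfer_function_summary",
    "accuracy_trait_enrichment",
]


@dataclass
class SizeFactorSet:
    factors: pd.Series
    n_reference_genes: int


def size_factors(counts: pd.DataFrame) -> SizeFactorSet:
    """Median-of-ratios size factors: for each sample, the median over
    all-nonzero genes of count / geometric-mean-across-samples."""
    if counts.shape[1] < 2:
        raise ValueError("need at least two samples")
    data = counts.astype(float)
    nonzero = (data > 0).all(axis=1)
    if not nonzero.any():
        raise ValueError(
            "no gene is nonzero in every sample; consider a pseudo-reference"
        )
    sub = data.loc[nonzero]
    log_gm = np.log(sub).mean(axis=1)
    ratios = np.log(sub).sub(log_gm, axis=0)
    factors = np.exp(ratios.median(axis=0))
    return SizeFactorSet(factors=factors, n_reference_genes=int(nonzero.sum()))


def scale_reference(
    bulk_frequencies: pd.Series, counts: pd.DataFrame, bulk_label: str = "bulk"
) -> tuple[pd.DataFrame, pd.Series]:
    """Normalize counts and the bulk reference onto a common scale.

    The bulk frequency vector joins the count matrix as a pseudo-sample
    for size-factor estimation; normalized counts and the scaled bulk
    expectation (per gene) are returned.  Scale-invariant in the bulk
    vector.
    """
    common = counts.index.intersection(bulk_frequencies.index)
    cts = counts.loc[common].astype(float)
    bulk = bulk_frequencies.loc[common].astype(float)
    bulk = bulk / bulk.sum()  # scale-invariant in the bulk vector
    augmented = cts.copy()
    augmented[bulk_label] = bulk
    sf = size_factors(augmented).factors
    normalized = cts / sf.drop(bulk_label)
    expected = bulk / sf[bulk_label]
    return normalized, expected


def fold_deviation(
    normalized_counts: pd.DataFrame,
    expected: pd.Series,
    mode: str = "per_replicate",
) -> pd.DataFrame:
    """Observed/expected fold deviation per gene.

    ``per_replicate``: one row per gene x sample, zeros excluded.
    ``average``: replicate counts are averaged first with zeros retained,
    then one fold deviation per gene.
    """
    expected = expected.reindex(normalized_counts.index)
    ok = expected > 0
    counts = normalized_counts.loc[ok]
    exp = expected.loc[ok]
    if mode == "per_replicate":
        long = counts.stack()
        long = long[long > 0]
        fd = long / exp.reindex(long.index.get_level_values(0)).to_numpy()
        out = fd.rename("fold_deviation").reset_index()
        out.columns = ["gene_id", "sample_id", "fold_deviation"]
        return out
    if mode == "average":
        avg = counts.mean(axis=1)
        fd = avg / exp
        fd = fd[avg > 0]
        return pd.DataFrame(
            {"gene_id": fd.index, "sample_id": "average", "fold_deviation": fd.to_numpy()}
        )
    raise ValueError(f"unknown mode {mode!r}")


def classify_accuracy(
    fold_table: pd.DataFrame,
    class_pct: float = 5.0,
    outlier_pct: float = 1.0,
    min_obs: int = 3,
) -> pd.DataFrame:
    """Over/underestimated classes from per-gene median fold deviations.

    Genes with fewer than ``min_obs`` observations are removed; the upper
    and lower ``class_pct`` percentile of median fold deviation are the
    over/underestimated classes, the ``outlier_pct`` tails are outliers.
    """
    per_gene = fold_table.groupby("gene_id")["fold_deviation"].agg(["median", "size"])
    per_gene = per_gene[per_gene["size"] >= min_obs]
    med = per_gene["median"]
    if med.empty:
        return pd.DataFrame(columns=["median_fold", "class", "outlier"])
    lo_c, hi_c = np.percentile(med, [class_pct, 100 - class_pct])
    lo_o, hi_o = np.percentile(med, [outlier_pct, 100 - outlier_pct])
    cls = np.select([med > hi_c, med < lo_c], ["over", "under"], default="background")
    return pd.DataFrame(
        {"median_fold": med, "class": cls, "outlier": (med > hi_o) | (med < lo_o)}
    )


def transfer_function_summary(
    molecules: pd.Series,
    normalized_counts: pd.DataFrame,
    fold_band: float = 2.0,
    n_bins: int = 20,
    reads_per_molecule: float | None = None,
) -> pd.DataFrame:
    """Input-molecules -> read-counts transfer function in log-spaced
    molecule bins: per-bin median normalized count and the fraction of
    observations within ``fold_band``-fold of the expected count.

    The expected count for a gene is its molecule count times the
    reads-per-molecule ratio — estimated globally as total normalized
    reads / total molecules unless supplied.
    """
    mol = molecules[molecules > 0]
    counts = normalized_counts.reindex(mol.index)
    if counts.isna().all().all():
        raise ValueError("count matrix shares no genes with the molecule table")
    if reads_per_molecule is None:
        scale = counts.to_numpy().sum() / (mol.sum() * counts.shape[1])
    else:
        scale = reads_per_molecule
    expected = mol * scale
    edges = np.geomspace(mol.min(), mol.max() * (1 + 1e-9), n_bins + 1)
    rows = []
    which = np.digitize(mol, edges) - 1
    for b in range(n_bins):
        genes = mol.index[which == b]
        if len(genes) == 0:
            continue
        obs = counts.loc[genes].to_numpy().ravel()
        exp = np.repeat(expected.loc[genes].to_numpy(), counts.shape[1])
        within = (obs >= exp / fold_band) & (obs <= exp * fold_band)
        rows.append(
            {
                "bin_low": edges[b],
                "bin_high": edges[b + 1],
                "n_genes": len(genes),
                "median_molecules": float(mol.loc[genes].median()),
                "median_count": float(np.median(obs)),
                "fraction_within_band": float(within.mean()),
            }
        )
    return pd.DataFrame(rows)


def accuracy_trait_enrichment(
    classes: pd.DataFrame, traits: pd.DataFrame
) -> dict[str, pd.DataFrame | str]:
    """Trait enrichment of over/underestimated classes vs background."""
    out: dict[str, pd.DataFrame | str] = {}
    background = classes.index[classes["class"] == "background"]
    for label in ("over", "under"):
        members = classes.index[classes["class"] == label]
        if len(members) < 2 or len(background) < 2:
            out[label] = "not-computable: class too small"
            continue
        out[label] = trait_enrichment(members, background, traits)
    return out
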