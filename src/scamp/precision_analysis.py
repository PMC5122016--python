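"""Replicate precision: correlations, mean-SD modeling, variability
classes, trait enrichment, PCA with bulk anchoring, and group comparisons.

Precision is assessed across dilution replicates of the same condition.
Pairwise similarity uses Pearson correlation on log10 depth-normalized
counts and Kendall rank correlation, with zeros treated as missing so
only genes observed in both members of a pair enter.  Replicate noise is
modeled as log10(SD) = a + b*log10(mean) across genes; genes whose
residual falls in the upper/lower 5% are classed as high/low variability
(1% tails are outliers, union-merged across input amounts), and classes
are tested for biophysical-trait enrichment (Hodges-Lehmann shift with
rank-sum p for continuous traits, relative risk with Fisher's exact test
for the A-hexamer flag).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CorrelationMatrix",
    "pairwise_correlations",
    "hodges_lehmann",
    "hodges_lehmann_paired",
    "mean_sd_regression",
    "classify_variability",
    "union_merge",
    "trait_enrichment",
    "pca_projection",
    "compare_groups",
]


@dataclass
class CorrelationMatrix:
    sample_ids: list
    matrix: pd.DataFrame
    kind: str
    zero_policy: str = "pairwise-missing"


def _kendall_tau_a(x: np.ndarray, y: np.ndarray) -> float:
    # Fraction concordant minus fraction discordant over all C(n,2) pairs.
    n = len(x)
    dx = np.sign(x[:, None] - x[None, :])
    dy = np.sign(y[:, None] - y[None, :])
    iu = np.triu_indices(n, 1)
    prod = dx[iu] * dy[iu]
    return float(prod.sum() / prod.size)


def pairwise_correlations(
    counts: pd.DataFrame,
    kind: str = "pearson",
    size_factors: pd.Series | None = None,
    kendall_variant: str = "b",
    min_joint: int = 3,
) -> CorrelationMatrix:
    """Pairwise replicate correlations with zeros treated as missing.

    Pearson runs on log10 of depth-normalized counts; Kendall on the raw
    normalized values (rank-based).  ``kendall_variant`` 'b' is the
    tie-corrected scipy tau-b; 'a' is plain concordant-minus-discordant
    pair counting.
    """
    data = counts.astype(float)
    if size_factors is not None:
        data = data / size_factors
    samples = list(data.columns)
    n = len(samples)
    mat = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            a, b = data.iloc[:, i], data.iloc[:, j]
            joint = (a > 0) & (b > 0)
            if joint.sum() < min_joint:
                warnings.warn(
                    f"pair ({samples[i]}, {samples[j]}): insufficient joint support"
                )
                mat[i, j] = mat[j, i] = np.nan
                continue
            x, y = a[joint].to_numpy(), b[joint].to_numpy()
            if kind == "pearson":
                r = stats.pearsonr(np.log10(x), np.log10(y)).statistic
            elif kind == "kendall":
                if kendall_variant == "a":
                    r = _kendall_tau_a(x, y)
                else:
                    r = stats.kendalltau(x, y, variant="b").statistic
            else:
                raise ValueError(f"unknown correlation kind {kind!r}")
            mat[i, j] = mat[j, i] = r
    return CorrelationMatrix(
        sample_ids=samples,
        matrix=pd.DataFrame(mat, index=samples, columns=samples),
        kind=kind if kind == "pearson" else f"kendall-{kendall_variant}",
    )


def hodges_lehmann(x, y, level: float = 0.95) -> dict:
    """Hodges-Lehmann estimate of the location difference x - y (median of
    all pairwise differences) with the distribution-free Moses CI."""
    x = np.sort(np.asarray(x, dtype=float))
    y = np.sort(np.asarray(y, dtype=float))
    m, n = len(x), len(y)
    diffs = np.sort((x[:, None] - y[None, :]).ravel())
    est = float(np.median(diffs))
    z = stats.norm.ppf(1 - (1 - level) / 2)
    k = m * n / 2 - z * np.sqrt(m * n * (m + n + 1) / 12.0)
    k = int(np.floor(k))
    k = max(k, 0)
    lo = diffs[k] if k < diffs.size else diffs[0]
    hi = diffs[m * n - 1 - k] if k < diffs.size else diffs[-1]
    return {"estimate": est, "ci_low": float(lo), "ci_high": float(hi)}


def hodges_lehmann_paired(differences, level: float = 0.95) -> dict:
    """Paired (one-sample) Hodges-Lehmann pseudo-median: the median of the
    Walsh averages of the paired differences, with the signed-rank CI."""
    d = np.sort(np.asarray(differences, dtype=float))
    n = len(d)
    walsh = np.sort(((d[:, None] + d[None, :]) / 2)[np.triu_indices(n)])
    est = float(np.median(walsh))
    z = stats.norm.ppf(1 - (1 - level) / 2)
    nw = walsh.size
    k = nw / 2 - z * np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0)
    k = max(int(np.floor(k)), 0)
    return {
        "estimate": est,
        "ci_low": float(walsh[k]) if k < nw else float(walsh[0]),
        "ci_high": float(walsh[nw - 1 - k]) if k < nw else float(walsh[-1]),
    }


def mean_sd_regression(
    counts_group: pd.DataFrame,
    presence_probability: pd.Series | None = None,
    exclude_genes=(),
    min_presence: float = 0.95,
    trim_pct: float = 2.5,
    min_samples: int = 5,
    min_genes: int = 50,
) -> dict:
    """Least-squares fit of log10(SD) on log10(mean) across genes.

    Filters, in order: genes with presence probability > ``min_presence``
    in a diluted replicate, detection outliers excluded, then the upper
    and lower ``trim_pct`` percentile by mean removed.  Groups smaller
    than ``min_samples`` replicates are skipped.
    """
    if counts_group.shape[1] < min_samples:
        return {"skipped": f"group has {counts_group.shape[1]} samples (<{min_samples})"}
    data = counts_group.astype(float)
    if presence_probability is not None:
        data = data.loc[presence_probability.reindex(data.index) > min_presence]
    data = data.drop(index=[g for g in exclude_genes if g in data.index])
    mean = data.mean(axis=1)
    sd = data.std(axis=1, ddof=1)
    lo, hi = np.percentile(mean, [trim_pct, 100 - trim_pct])
    keep = mean.between(lo, hi) & (mean > 0) & (sd > 0)
    mean, sd = mean[keep], sd[keep]
    if len(mean) < min_genes:
        raise ValueError(f"only {len(mean)} genes after filtering (<{min_genes})")
    lx, ly = np.log10(mean), np.log10(sd)
    fit = stats.linregress(lx, ly)
    residuals = ly - (fit.intercept + fit.slope * lx)
    return {
        "intercept": float(fit.intercept),
        "slope": float(fit.slope),
        "r_squared": float(fit.rvalue**2),
        "slope_p": float(fit.pvalue),
        "n_genes": int(len(mean)),
        "residuals": pd.Series(residuals, index=mean.index),
        "mean": mean,
        "sd": sd,
    }


def classify_variability(
    residuals: pd.Series, class_pct: float = 5.0, outlier_pct: float = 1.0
) -> pd.DataFrame:
    """Percentile classes on mean-SD residuals: upper/lower ``class_pct``
    are high/low experimental variability, the rest background; the
    ``outlier_pct`` tails are flagged as outliers.  Ties are broken by
    gene id for determinism."""
    res = residuals.sort_values(kind="mergesort")
    res = res.loc[sorted(res.index)].sort_values(kind="mergesort")
    lo_c, hi_c = np.percentile(res, [class_pct, 100 - class_pct])
    lo_o, hi_o = np.percentile(res, [outlier_pct, 100 - outlier_pct])
    cls = np.select(
        [res > hi_c, res < lo_c], ["high", "low"], default="background"
    )
    out = (res > hi_o) | (res < lo_o)
    return pd.DataFrame({"residual": res, "class": cls, "outlier": out})


def union_merge(*outlier_sets) -> set:
    """Union of outlier gene sets (merging across input amounts)."""
    merged: set = set()
    for s in outlier_sets:
        merged |= set(s)
    return merged


def trait_enrichment(
    class_genes, background_genes, traits: pd.DataFrame,
    continuous=("L", "G", "S"), binary=("A",),
) -> pd.DataFrame:
    """Per-trait enrichment of a gene class against background.

    Continuous traits: Hodges-Lehmann location difference with CI plus a
    two-sided Wilcoxon rank-sum p.  Binary traits: relative risk with
    Fisher's exact p.
    """
    cg = [g for g in class_genes if g in traits.index]
    bg = [g for g in background_genes if g in traits.index]
    if len(cg) < 2 or len(bg) < 2:
        raise ValueError("both groups need at least two genes")
    rows = []
    for t in continuous:
        x, y = traits.loc[cg, t], traits.loc[bg, t]
        hl = hodges_lehmann(x, y)
        p = stats.mannwhitneyu(x, y, alternative="two-sided").pvalue
        rows.append({"trait": t, "statistic": "hodges_lehmann",
                     "estimate": hl["estimate"], "ci_low": hl["ci_low"],
                     "ci_high": hl["ci_high"], "p": float(p)})
    for t in binary:
        a = int(traits.loc[cg, t].sum()); b = len(cg) - a
        c = int(traits.loc[bg, t].sum()); d = len(bg) - c
        p = stats.fisher_exact([[a, b], [c, d]])[1]
        if a + b == 0 or c + d == 0 or c == 0:
            rr, lo, hi = np.nan, np.nan, np.nan
        else:
            rr = (a / (a + b)) / (c / (c + d))
            if a == 0:
                lo = hi = np.nan
            else:
                se = np.sqrt(max(1 / a - 1 / (a + b) + 1 / c - 1 / (c + d), 0.0))
                lo, hi = rr * np.exp(-1.96 * se), rr * np.exp(1.96 * se)
        rows.append({"trait": t, "statistic": "relative_risk", "estimate": rr,
                     "ci_low": lo, "ci_high": hi, "p": float(p)})
    return pd.DataFrame(rows)


def pca_projection(
    log_counts: pd.DataFrame, bulk_column: str, groups: dict | None = None,
    level: float = 0.95,
) -> dict:
    """PCA of samples (zero-corrected log counts), centered so the bulk
    sample sits at the origin, with bivariate-normal confidence ellipses
    per experimental group.

    ``log_counts``: genes x samples, already log-transformed; must include
    ``bulk_column``.  ``groups`` maps group label -> list of sample ids.
    """
    X = log_counts.T.to_numpy(dtype=float)  # samples x genes
    samples = list(log_counts.columns)
    if bulk_column not in samples:
        raise ValueError(f"bulk column {bulk_column!r} missing")
    Xc = X - X.mean(axis=0)
    cov = np.cov(Xc, rowvar=True)  # sample covariance (samples x samples)
    # Eigendecomposition via SVD of the centered matrix for scores.
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = s**2 / (X.shape[0] - 1)
    keep = s > 1e-10 * s.max()
    scores = (U[:, keep] * s[keep])
    scores = pd.DataFrame(
        scores, index=samples,
        columns=[f"PC{i+1}" for i in range(scores.shape[1])],
    )
    scores = scores - scores.loc[bulk_column]
    frac = var[keep] / var.sum()
    ellipses = {}
    if groups:
        chi2_q = stats.chi2.ppf(level, df=2)
        for label, members in groups.items():
            pts = scores.loc[[m for m in members if m in scores.index], ["PC1", "PC2"]]
            if len(pts) < 3:
                continue
            center = pts.mean()
            c2 = np.cov(pts.to_numpy().T)
            evals, evecs = np.linalg.eigh(c2)
            order = np.argsort(evals)[::-1]
            evals, evecs = evals[order], evecs[:, order]
            ellipses[label] = {
                "center": center.tolist(),
                "semi_axes": list(np.sqrt(np.maximum(evals, 0) * chi2_q)),
                "angle_rad": float(np.arctan2(evecs[1, 0], evecs[0, 0])),
            }
    return {
        "scores": scores,
        "variance_fraction": frac,
        "ellipses": ellipses,
    }


def compare_groups(a, b, paired: bool = False, level: float = 0.95) -> dict:
    """Wilcoxon comparison of a metric between two groups of samples with
    a Hodges-Lehmann difference estimate and CI.

    Unpaired: two-sided rank-sum; paired: two-sided signed-rank on the
    elementwise differences.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two values")
    if paired:
        if len(a) != len(b):
            raise ValueError("paired comparison requires equal lengths")
        d = a - b
        if np.allclose(d, 0):
            p = 1.0
        else:
            p = float(stats.wilcoxon(a, b, alternative="two-sided").pvalue)
        hl = hodges_lehmann_paired(d, level)
        test = "wilcoxon-signed-rank"
    else:
        p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
        hl = hodges_lehmann(a, b, level)
        test = "wilcoxon-rank-sum"
    return {"test": test, "p": p, "significant": p < 0.05, **hl}
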