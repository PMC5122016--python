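"""Fractional-polynomial logistic model of gene detection.

Detection of a gene in a diluted replicate is modeled as Bernoulli with

    logit P(Y=1) = b0 + b1*sqrt(M) + b2*log(M)*sqrt(M) + b3*log(L)
                 + b4*G^-2 + b5*log(G)*G^-2 + b6*(S + 39.1)/10
                 + b7*A + b8*(D/10)^-2

where M is the expected number of input molecules, L the gene length in
kilobases, G the GC fraction, S the mean local secondary-structure
strength (kcal/mol), A the internal A-hexamer indicator and D the
sequencing depth in millions of reads.  The functional form is the final
model selected by a multivariable fractional-polynomial search and is
treated as fixed here; logs are natural.  Amplification methods get their
own coefficient set for every term except depth, which is shared.

The module also provides the fit diagnostics used to interrogate such a
model: Cook's-distance influence screening, normalized chi-square and
sum-of-squares goodness-of-fit on a holdout split, bootstrap AUC, odds
ratios with delta-method intervals, depth-gain extrapolation, the
50%-detection point, the molecular recovery rate, and the squared
deviance-residual outlier catalogue.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats

__all__ = [
    "TERM_NAMES",
    "DetectionModelFit",
    "build_design_row",
    "build_design_matrix",
    "trim_covariates",
    "train_validation_split",
    "fit_detection_glm",
    "cooks_exclusion",
    "goodness_of_fit",
    "auc_bootstrap",
    "predict_detection",
    "fifty_percent_point",
    "molecular_recovery_rate",
    "odds_ratio",
    "compare_method_effects",
    "expected_gain_with_depth",
    "squared_deviance_residuals",
    "classify_detection_outliers",
    "outlier_context_tests",
]

# Fixed transformed basis, in reporting order.  The structure shift and the
# depth scaling are part of the selected functional form.
STRUCTURE_SHIFT = 39.1
TERM_NAMES = (
    "const",
    "sqrt_M",
    "logM_sqrt_M",
    "log_L",
    "G_inv2",
    "logG_G_inv2",
    "S_shifted",
    "A",
    "depth_inv2",
)
N_METHOD_TERMS = 8  # all but the shared depth term

OBS_COLUMNS = ("gene_id", "sample_id", "method", "Y", "M", "L", "G", "S", "A", "D")


def build_design_row(M, L, G, S, A, D) -> np.ndarray:
    """The 9 transformed covariate terms (incl. intercept), vectorized.

    Returns an array of shape (..., 9) in :data:`TERM_NAMES` order.
    """
    M = np.asarray(M, dtype=float)
    L = np.asarray(L, dtype=float)
    G = np.asarray(G, dtype=float)
    S = np.asarray(S, dtype=float)
    A = np.asarray(A, dtype=float)
    D = np.asarray(D, dtype=float)
    for name, arr, ok in (
        ("M", M, M > 0),
        ("L", L, L > 0),
        ("G", G, (G > 0) & (G <= 1)),
        ("D", D, D > 0),
    ):
        if not np.all(ok):
            raise ValueError(f"covariate {name} outside its domain")
    sqrt_m = np.sqrt(M)
    g_inv2 = G**-2.0
    rows = np.stack(
        np.broadcast_arrays(
            np.ones_like(M),
            sqrt_m,
            np.log(M) * sqrt_m,
            np.log(L),
            g_inv2,
            np.log(G) * g_inv2,
            (S + STRUCTURE_SHIFT) / 10.0,
            A,
            (D / 10.0) ** -2.0,
        ),
        axis=-1,
    )
    return rows


def build_design_matrix(
    observations: pd.DataFrame, methods: list[str]
) -> tuple[np.ndarray, list[str]]:
    """Full-interaction design: one coefficient set per method for every
    term except depth, which is a single shared column."""
    base = build_design_row(
        observations["M"], observations["L"], observations["G"],
        observations["S"], observations["A"], observations["D"],
    )
    n = len(observations)
    X = np.zeros((n, len(methods) * N_METHOD_TERMS + 1))
    names: list[str] = []
    for j, m in enumerate(methods):
        mask = (observations["method"] == m).to_numpy()
        X[mask, j * N_METHOD_TERMS : (j + 1) * N_METHOD_TERMS] = base[
            mask, :N_METHOD_TERMS
        ]
        names.extend(f"{m}:{t}" for t in TERM_NAMES[:N_METHOD_TERMS])
    X[:, -1] = base[:, -1]
    names.append(TERM_NAMES[-1])
    return X, names


@dataclass
class DetectionModelFit:
    """A fitted detection model with everything needed to interrogate it."""

    result: object  # statsmodels GLMResults
    methods: list[str]
    column_names: list[str]
    covariate_medians: dict  # training medians of L, G, S, A, D
    trim_bounds: pd.DataFrame | None
    excluded_genes: list = field(default_factory=list)
    split_seed: int | None = None
    holdout_index: np.ndarray | None = None
    diagnostics: dict = field(default_factory=dict)

    @property
    def params(self) -> pd.Series:
        return pd.Series(self.result.params, index=self.column_names)

    @property
    def cov_params(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.result.cov_params(), index=self.column_names,
            columns=self.column_names,
        )

    def coefficients(self) -> pd.DataFrame:
        """Coefficient table: rows = terms, one column per method (the
        shared depth coefficient is repeated in each column)."""
        p = self.params
        table = {}
        for m in self.methods:
            col = [p[f"{m}:{t}"] for t in TERM_NAMES[:N_METHOD_TERMS]]
            col.append(p[TERM_NAMES[-1]])
            table[m] = col
        return pd.DataFrame(table, index=list(TERM_NAMES))

    def method_beta(self, method: str) -> np.ndarray:
        if method not in self.methods:
            raise KeyError(f"unknown method label: {method!r}")
        return self.coefficients()[method].to_numpy()


def trim_covariates(
    observations: pd.DataFrame, pct: float = 2.5
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop genes in the upper or lower ``pct`` percentile on any of the
    biophysical traits (M, L, G, S), so covariate ranges are well sampled.

    Trimming is per-trait at the gene level, and a gene outside the band on
    any trait is removed (union of removals).  Returns (filtered
    observations, trim-bound table).
    """
    gene_traits = observations.groupby("gene_id")[["M", "L", "G", "S"]].mean()
    if len(gene_traits) < 40:
        raise ValueError("too few genes for percentile trimming")
    bounds = {}
    keep = pd.Series(True, index=gene_traits.index)
    for trait in ("M", "L", "G", "S"):
        lo, hi = np.percentile(gene_traits[trait], [pct, 100 - pct])
        bounds[trait] = (lo, hi)
        keep &= gene_traits[trait].between(lo, hi)
    kept_genes = gene_traits.index[keep]
    out = observations[observations["gene_id"].isin(kept_genes)]
    if out.empty:
        raise ValueError("trimming removed all observations")
    btab = pd.DataFrame(bounds, index=["lower", "upper"]).T
    return out.reset_index(drop=True), btab


def train_validation_split(
    observations: pd.DataFrame, holdout_fraction: float = 0.1, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Random observation-level split for model development / validation."""
    rng = np.random.default_rng(seed)
    n = len(observations)
    idx = rng.permutation(n)
    n_hold = int(round(n * holdout_fraction))
    hold = observations.iloc[idx[:n_hold]].reset_index(drop=True)
    train = observations.iloc[idx[n_hold:]].reset_index(drop=True)
    return train, hold


def fit_detection_glm(
    observations: pd.DataFrame,
    methods: list[str] | None = None,
    split_seed: int = 0,
    holdout_fraction: float = 0.1,
    trim_bounds: pd.DataFrame | None = None,
) -> DetectionModelFit:
    """Maximum-likelihood logistic fit on the fixed transformed basis.

    ``observations`` must hold the columns in :data:`OBS_COLUMNS` (already
    filtered/trimmed).  A random ``holdout_fraction`` of observations is
    held out for goodness-of-fit assessment.
    """
    if methods is None:
        methods = sorted(observations["method"].unique())
    for m in methods:
        y = observations.loc[observations["method"] == m, "Y"]
        if y.sum() < 2 or (1 - y).sum() < 2:
            raise ValueError(
                f"method {m!r} lacks two outcomes of each detection class"
            )
    train, hold = (
        train_validation_split(observations, holdout_fraction, split_seed)
        if holdout_fraction > 0
        else (observations, observations.iloc[0:0])
    )
    X, names = build_design_matrix(train, methods)
    model = sm.GLM(train["Y"].to_numpy(dtype=float), X, family=sm.families.Binomial())
    result = model.fit(maxiter=200)
    if not result.converged:
        raise RuntimeError(
            f"logistic fit did not converge in {result.fit_history['iteration']} "
            "iterations"
        )
    if np.any(np.abs(result.params) > 1e4):
        big = [names[i] for i in np.flatnonzero(np.abs(result.params) > 1e4)]
        raise RuntimeError(f"possible perfect separation; runaway terms: {big}")
    medians = {
        "L": float(train["L"].median()),
        "G": float(train["G"].median()),
        "S": float(train["S"].median()),
        "A": 0.0,
        "D": float(train["D"].median()),
    }
    fit = DetectionModelFit(
        result=result,
        methods=methods,
        column_names=names,
        covariate_medians=medians,
        trim_bounds=trim_bounds,
        split_seed=split_seed,
        holdout_index=None,
    )
    fit.train = train
    fit.holdout = hold
    return fit


def cooks_exclusion(
    fit: DetectionModelFit,
    observations: pd.DataFrame | None = None,
    threshold: float = 0.001,
    min_obs: int = 2,
    min_methods: int = 2,
    cooks: np.ndarray | None = None,
) -> list:
    """Genes with Cook's distance above ``threshold`` for at least
    ``min_obs`` observations in each of at least ``min_methods`` methods.

    Cook's distances are computed on the training data unless supplied
    via ``cooks``.  The caller is expected to refit without the returned
    genes.
    """
    obs = fit.train if observations is None else observations
    if cooks is None:
        influence = fit.result.get_influence(observed=False)
        cooks = influence.cooks_distance[0]
    flagged = pd.DataFrame(
        {"gene_id": obs["gene_id"].to_numpy(), "method": obs["method"].to_numpy(),
         "high": cooks > threshold}
    )
    per = flagged.groupby(["gene_id", "method"])["high"].sum().unstack(fill_value=0)
    n_methods_over = (per >= min_obs).sum(axis=1)
    return sorted(n_methods_over.index[n_methods_over >= min_methods])


def _holdout_probs(fit: DetectionModelFit, holdout: pd.DataFrame) -> np.ndarray:
    X, _ = build_design_matrix(holdout, fit.methods)
    eta = X @ np.asarray(fit.result.params)
    return 1.0 / (1.0 + np.exp(-eta))


def goodness_of_fit(
    fit: DetectionModelFit, holdout: pd.DataFrame | None = None
) -> dict:
    """Normalized (standardized) chi-square and sum-of-squares
    goodness-of-fit on held-out data.

    On a holdout disjoint from training the coefficients are fixed, so the
    Pearson chi-square X2 = sum (y - p)^2 / (p(1-p)) and the unweighted
    sum-of-squares S = sum (y - p)^2 have exact null Bernoulli moments:
    per-observation variance (1 - 4pq)/(pq) and pq(1 - 4pq) respectively.
    Each statistic is standardized by those moments and referred to the
    standard normal (two-sided).
    """
    hold = fit.holdout if holdout is None else holdout
    if len(hold) == 0:
        raise ValueError("empty holdout")
    p = np.clip(_holdout_probs(fit, hold), 1e-12, 1 - 1e-12)
    y = hold["Y"].to_numpy(dtype=float)
    q = 1 - p
    v = p * q
    if np.all(v < 1e-12):
        raise ValueError("degenerate holdout: fitted probabilities constant 0/1")
    x2 = float(np.sum((y - p) ** 2 / v))
    var_x2 = float(np.sum((1 - 4 * v) / v))
    z_x2 = (x2 - len(hold)) / np.sqrt(var_x2)
    ssq = float(np.sum((y - p) ** 2))
    var_ssq = float(np.sum(v * (1 - 4 * v)))
    z_ssq = (ssq - float(v.sum())) / np.sqrt(var_ssq)
    return {
        "chi_square": x2,
        "chi_square_z": z_x2,
        "chi_square_p": 2 * stats.norm.sf(abs(z_x2)),
        "sum_of_squares": ssq,
        "sum_of_squares_z": z_ssq,
        "sum_of_squares_p": 2 * stats.norm.sf(abs(z_ssq)),
        "n": len(hold),
    }


def _auc(y: np.ndarray, score: np.ndarray) -> float:
    # Concordance probability via the rank-sum identity (tie-corrected).
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("holdout must contain both detection classes")
    ranks = stats.rankdata(score)
    return (ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)


def auc_bootstrap(
    fit: DetectionModelFit,
    holdout: pd.DataFrame | None = None,
    n_boot: int = 10_000,
    seed: int | None = None,
) -> dict:
    """Bootstrap mean and sd of the AUC on held-out data, for the full
    model and for ranking by expected input molecules alone."""
    hold = fit.holdout if holdout is None else holdout
    y = hold["Y"].to_numpy(dtype=float)
    if y.sum() in (0, len(y)):
        raise ValueError("holdout must contain both detection classes")
    scores = {"full_model": _holdout_probs(fit, hold), "molecules_only": hold["M"].to_numpy(dtype=float)}
    rng = np.random.default_rng(seed)
    out = {}
    n = len(y)
    idx = rng.integers(0, n, size=(n_boot, n))
    for label, s in scores.items():
        aucs = np.empty(n_boot)
        for b in range(n_boot):
            i = idx[b]
            yb = y[i]
            if yb.sum() in (0, n):
                aucs[b] = np.nan
                continue
            aucs[b] = _auc(yb, s[i])
        out[label] = (float(np.nanmean(aucs)), float(np.nanstd(aucs)))
    return out


def predict_detection(fit: DetectionModelFit, method: str, M, L=None, G=None,
                      S=None, A=None, D=None) -> np.ndarray | float:
    """Detection probability from the fitted model; unspecified covariates
    default to the training medians (hexamer absent)."""
    med = fit.covariate_medians
    L = med["L"] if L is None else L
    G = med["G"] if G is None else G
    S = med["S"] if S is None else S
    A = med["A"] if A is None else A
    D = med["D"] if D is None else D
    beta = fit.method_beta(method)
    x = build_design_row(M, L, G, S, A, D)
    eta = x @ beta
    p = 1.0 / (1.0 + np.exp(-eta))
    return float(p) if np.ndim(p) == 0 else p


def fifty_percent_point(
    fit: DetectionModelFit, method: str, m_max: float = 1e4, **covariates
) -> float:
    """Expected input molecules at which detection probability crosses 50%
    (remaining covariates at their medians), by bracketed root finding."""
    f = lambda m: predict_detection(fit, method, m, **covariates) - 0.5
    grid = np.geomspace(1e-6, m_max, 200)
    vals = np.array([f(m) for m in grid])
    sign_change = np.flatnonzero(np.sign(vals[:-1]) * np.sign(vals[1:]) < 0)
    if len(sign_change) == 0:
        raise ValueError("detection curve does not cross 50% on the search range")
    i = sign_change[0]
    return float(optimize.brentq(f, grid[i], grid[i + 1], rtol=1e-9))


def molecular_recovery_rate(fit: DetectionModelFit, method: str, **covariates) -> float:
    """Predicted detection probability at M = 1 scaled by the probability
    that at least one molecule of such a gene is in the tube (1 - 1/e)."""
    p1 = predict_detection(fit, method, 1.0, **covariates)
    return p1 / (1.0 - np.exp(-1.0))


def _delta_x(fit: DetectionModelFit, method: str, covariate: str,
             from_value: float, to_value: float) -> np.ndarray:
    """Change in the full coefficient-vector design under a change of one
    raw covariate, all others held at medians."""
    med = dict(fit.covariate_medians)
    med.setdefault("M", 1.0)
    base = {k: med[k] for k in ("L", "G", "S", "A", "D")}
    base["M"] = med["M"]
    if covariate not in base:
        raise KeyError(f"unknown covariate {covariate!r}")
    lo, hi = dict(base), dict(base)
    lo[covariate] = from_value
    hi[covariate] = to_value
    row = lambda c: build_design_row(c["M"], c["L"], c["G"], c["S"], c["A"], c["D"])
    dx_terms = row(hi) - row(lo)
    dx = np.zeros(len(fit.column_names))
    j = fit.methods.index(method) * N_METHOD_TERMS
    dx[j : j + N_METHOD_TERMS] = dx_terms[:N_METHOD_TERMS]
    dx[-1] = dx_terms[-1]
    return dx


def odds_ratio(
    fit: DetectionModelFit,
    method: str,
    covariate: str,
    from_value: float,
    to_value: float,
    level: float = 0.95,
) -> dict:
    """Odds ratio for changing one covariate, with a delta-method CI on
    the log scale."""
    dx = _delta_x(fit, method, covariate, from_value, to_value)
    beta = np.asarray(fit.result.params)
    log_or = float(dx @ beta)
    se = float(np.sqrt(dx @ fit.result.cov_params() @ dx))
    z = stats.norm.ppf(1 - (1 - level) / 2)
    return {
        "odds_ratio": np.exp(log_or),
        "ci_low": np.exp(log_or - z * se),
        "ci_high": np.exp(log_or + z * se),
        "log_or": log_or,
        "se": se,
    }


def compare_method_effects(
    fit: DetectionModelFit, covariate: str, from_value: float, to_value: float,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pairwise tests of whether the covariate's odds ratio differs across
    methods, Bonferroni-corrected over the method pairs."""
    cov = fit.result.cov_params()
    beta = np.asarray(fit.result.params)
    rows = []
    pairs = [
        (a, b)
        for i, a in enumerate(fit.methods)
        for b in fit.methods[i + 1 :]
    ]
    for a, b in pairs:
        d = _delta_x(fit, a, covariate, from_value, to_value) - _delta_x(
            fit, b, covariate, from_value, to_value
        )
        est = float(d @ beta)
        se = float(np.sqrt(d @ cov @ d))
        z = est / se if se > 0 else np.nan
        p = 2 * stats.norm.sf(abs(z))
        rows.append(
            {"method_a": a, "method_b": b, "log_or_difference": est, "se": se,
             "z": z, "p": p, "p_bonferroni": min(1.0, p * len(pairs)),
             "significant": p * len(pairs) < alpha}
        )
    return pd.DataFrame(rows)


def expected_gain_with_depth(
    fit: DetectionModelFit,
    observations: pd.DataFrame,
    depth_from: float,
    depth_to: float,
) -> float:
    """Percent gain in the expected number of detected genes when depth
    moves from ``depth_from`` to ``depth_to`` million reads: detection
    probabilities are computed per gene at each depth with gene-specific
    covariates, and the expected detected count is their sum."""
    if depth_from <= 0 or depth_to <= 0:
        raise ValueError("depths must be positive")

    def expected(depth: float) -> float:
        total = 0.0
        for m in fit.methods:
            sub = observations[observations["method"] == m]
            if sub.empty:
                continue
            p = predict_detection(
                fit, m, sub["M"].to_numpy(), sub["L"].to_numpy(),
                sub["G"].to_numpy(), sub["S"].to_numpy(), sub["A"].to_numpy(),
                depth,
            )
            total += float(np.sum(p))
        return total

    base = expected(depth_from)
    return 100.0 * (expected(depth_to) - base) / base


def squared_deviance_residuals(y, p_hat) -> np.ndarray:
    """Per-observation squared deviance residual
    d^2 = -2 [ y ln p + (1-y) ln(1-p) ]; their sum is the model deviance."""
    y = np.asarray(y, dtype=float)
    p = np.asarray(p_hat, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        d2 = -2.0 * (y * np.log(p) + (1 - y) * np.log1p(-p))
    # A fitted probability of exactly 0/1 against the opposite outcome is an
    # infinite residual; keep it as inf so callers can flag it.
    return np.where(np.isnan(d2), 0.0, d2)


def classify_detection_outliers(
    observations: pd.DataFrame, d2: np.ndarray, threshold: float = 4.0
) -> pd.DataFrame:
    """Method-specific detection outliers: genes whose average squared
    deviance residual over all of a method's observations exceeds the
    threshold (strictly).  Each outlier is labeled 'detected' if its
    majority observed state among that method's observations is detection,
    'undetected' if missing, 'mixed' on a tie."""
    tab = observations[["gene_id", "method", "Y"]].copy()
    tab["d2"] = np.asarray(d2, dtype=float)
    per = tab.groupby(["gene_id", "method"]).agg(
        mean_d2=("d2", "mean"), mean_y=("Y", "mean"), n=("Y", "size")
    )
    out = per[per["mean_d2"] > threshold].reset_index()
    out["label"] = np.select(
        [out["mean_y"] > 0.5, out["mean_y"] < 0.5], ["detected", "undetected"],
        default="mixed",
    )
    return out[["gene_id", "method", "mean_d2", "label", "n"]]


def outlier_context_tests(
    outlier_traits: pd.DataFrame, background_traits: pd.DataFrame,
    metrics: tuple[str, ...] = ("mappability_fraction", "overlap_fraction"),
) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum tests comparing ambiguity metrics of
    outlier genes against background genes."""
    if len(outlier_traits) < 2 or len(background_traits) < 2:
        raise ValueError("both groups need at least two genes")
    rows = []
    for metric in metrics:
        res = stats.mannwhitneyu(
            outlier_traits[metric], background_traits[metric],
            alternative="two-sided",
        )
        rows.append(
            {"metric": metric, "statistic": float(res.statistic),
             "p": float(res.pvalue),
             "outlier_median": float(outlier_traits[metric].median()),
             "background_median": float(background_traits[metric].median())}
        )
    return pd.DataFrame(rows)
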