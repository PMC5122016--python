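import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from scamp.precision_analysis import (
    pairwise_correlations,
    _kendall_tau_a,
    hodges_lehmann,
    hodges_lehmann_paired,
    mean_sd_regression,
    classify_variability,
    union_merge,
    trait_enrichment,
    pca_projection,
    compare_groups,
)


class TestCorrelations:
    def _counts(self, n=200, seed=0):
        rng = np.random.default_rng(seed)
        base = rng.lognormal(3, 1, n)
        return pd.DataFrame(
            {f"s{i}": rng.poisson(base) for i in range(4)},
            index=[f"g{i}" for i in range(n)],
        )

    def test_self_correlation(self):
        counts = self._counts()
        counts["dup"] = counts["s0"]
        for kind in ("pearson", "kendall"):
            m = pairwise_correlations(counts[["s0", "dup"]], kind).matrix
            assert m.loc["s0", "dup"] == pytest.approx(1.0)

    def test_rank_reversal_kendall_minus_one(self):
        counts = pd.DataFrame({"a": np.arange(1, 11), "b": np.arange(10, 0, -1)})
        m = pairwise_correlations(counts, "kendall").matrix
        assert m.loc["a", "b"] == pytest.approx(-1.0)

    def test_kendall_brute_force_oracle(self):
        """Tau on tie-free data equals explicit concordant/discordant pair
        counting (tau-a = tau-b without ties), up to n=200."""
        rng = np.random.default_rng(1)
        x = rng.permutation(200).astype(float) + 1
        y = rng.permutation(200).astype(float) + 1
        counts = pd.DataFrame({"a": x, "b": y})
        m = pairwise_correlations(counts, "kendall").matrix
        conc = disc = 0
        for i, j in itertools.combinations(range(200), 2):
            s = np.sign(x[i] - x[j]) * np.sign(y[i] - y[j])
            conc += s > 0
            disc += s < 0
        brute = (conc - disc) / (200 * 199 / 2)
        assert m.loc["a", "b"] == pytest.approx(brute, abs=1e-12)
        m_a = pairwise_correlations(counts, "kendall", kendall_variant="a").matrix
        assert m_a.loc["a", "b"] == pytest.approx(brute, abs=1e-12)

    def test_zeros_treated_as_missing(self):
        counts = pd.DataFrame(
            {"a": [0, 10, 20, 30, 5, 8], "b": [100, 11, 19, 33, 6, 0]}
        )
        m = pairwise_correlations(counts, "pearson").matrix
        joint = counts[(counts > 0).all(axis=1)]
        expected = stats.pearsonr(
            np.log10(joint["a"]), np.log10(joint["b"])
        ).statistic
        assert m.loc["a", "b"] == pytest.approx(expected)


class TestHodgesLehmann:
    def test_nine_pair_enumeration(self):
        out = hodges_lehmann([1, 2, 3], [4, 5, 6])
        diffs = sorted(a - b for a in (1, 2, 3) for b in (4, 5, 6))
        assert out["estimate"] == np.median(diffs) == -3

    def test_identical_groups_zero(self):
        x = [1.0, 2.0, 5.0, 9.0]
        assert hodges_lehmann(x, x)["estimate"] == 0.0

    def test_shift_recovery_with_ci(self):
        rng = np.random.default_rng(2)
        x = rng.normal(5, 1, 60)
        y = rng.normal(0, 1, 60)
        out = hodges_lehmann(x, y)
        assert out["ci_low"] < 5 < out["ci_high"]
        assert out["estimate"] == pytest.approx(5, abs=0.5)

    def test_paired_walsh_average(self):
        d = np.array([1.0, 2.0, 10.0])
        walsh = sorted(
            (d[i] + d[j]) / 2 for i in range(3) for j in range(i, 3)
        )
        assert hodges_lehmann_paired(d)["estimate"] == np.median(walsh)


class TestMeanSdRegression:
    def test_exact_power_law(self):
        rng = np.random.default_rng(3)
        mean = rng.lognormal(3, 1, 200)
        # multipliers with exact mean 0 and sample sd 1 -> SD = 0.3 * mean
        z = np.array([-1.0, 1, -1, 1, -1, 1]) / np.sqrt(1.2)
        counts = pd.DataFrame(
            {f"s{i}": mean * (1 + 0.3 * z[i]) for i in range(6)},
            index=[f"g{i}" for i in range(200)],
        )
        out = mean_sd_regression(counts, trim_pct=0.5)
        assert out["slope"] == pytest.approx(1.0, abs=1e-6)
        assert out["r_squared"] == pytest.approx(1.0, abs=1e-9)
        assert np.allclose(out["residuals"], 0, atol=1e-9)

    def test_poisson_slope_half(self):
        rng = np.random.default_rng(4)
        lam = rng.lognormal(4, 1, 2000)
        counts = pd.DataFrame(
            rng.poisson(lam[:, None], (2000, 30)).astype(float),
            index=[f"g{i}" for i in range(2000)],
            columns=[f"s{i}" for i in range(30)],
        )
        out = mean_sd_regression(counts)
        assert out["slope"] == pytest.approx(0.5, abs=0.05)

    def test_small_group_skipped(self):
        counts = pd.DataFrame(np.ones((10, 3)))
        out = mean_sd_regression(counts)
        assert "skipped" in out


class TestVariabilityClasses:
    def test_percentile_arithmetic(self):
        rng = np.random.default_rng(5)
        res = pd.Series(rng.normal(size=100), index=[f"g{i:03d}" for i in range(100)])
        out = classify_variability(res)
        assert (out["class"] == "high").sum() == 5
        assert (out["class"] == "low").sum() == 5
        assert out["outlier"].sum() == 2

    def test_degenerate_ties(self):
        res = pd.Series(np.zeros(50), index=[f"g{i}" for i in range(50)])
        out = classify_variability(res)
        assert (out["class"] == "background").all()

    def test_union_merge(self):
        assert union_merge({"g1", "g2"}, {"g2", "g3"}) == {"g1", "g2", "g3"}


class TestTraitEnrichment:
    def _traits(self, n=60, seed=6):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            {
                "L": rng.lognormal(0, 0.5, n),
                "G": rng.beta(10, 10, n),
                "S": rng.normal(-25, 5, n),
                "A": rng.integers(0, 2, n),
            },
            index=[f"g{i}" for i in range(n)],
        )

    def test_identical_groups_null(self):
        traits = self._traits()
        genes = list(traits.index[:30])
        out = trait_enrichment(genes, genes, traits).set_index("trait")
        assert out.loc["L", "estimate"] == pytest.approx(0.0, abs=1e-9)
        assert out.loc["A", "estimate"] == pytest.approx(1.0)

    def test_relative_risk_closed_form(self):
        traits = pd.DataFrame(
            {"L": 1.0, "G": 0.5, "S": -25.0,
             "A": [1] * 8 + [0] * 2 + [1] * 2 + [0] * 8},
            index=[f"g{i}" for i in range(20)],
        )
        cls = [f"g{i}" for i in range(10)]
        bg = [f"g{i}" for i in range(10, 20)]
        out = trait_enrichment(cls, bg, traits).set_index("trait")
        assert out.loc["A", "estimate"] == pytest.approx(4.0)
        table_p = stats.fisher_exact([[8, 2], [2, 8]])[1]
        assert out.loc["A", "p"] == pytest.approx(table_p)


class TestPca:
    def _log_counts(self, seed=7):
        rng = np.random.default_rng(seed)
        base = rng.normal(3, 1, 100)
        cols = {"bulk": base}
        for i in range(4):
            cols[f"a{i}"] = base + rng.normal(0, 0.1, 100) + (0.5 if i < 2 else -0.5)
        return pd.DataFrame(cols)

    def test_bulk_at_origin(self):
        out = pca_projection(self._log_counts(), "bulk")
        assert np.allclose(out["scores"].loc["bulk"], 0.0, atol=1e-9)

    def test_variance_fractions_sum_to_one(self):
        out = pca_projection(self._log_counts(), "bulk")
        assert out["variance_fraction"].sum() == pytest.approx(1.0)

    def test_cluster_separation_and_eigen_oracle(self):
        rng = np.random.default_rng(8)
        base = rng.normal(3, 1, 200)
        cols = {"bulk": base}
        for i in range(6):
            shift = 2.0 if i < 3 else -2.0
            cols[f"s{i}"] = base + shift + rng.normal(0, 0.05, 200)
        lc = pd.DataFrame(cols)
        groups = {"up": [f"s{i}" for i in range(3)],
                  "down": [f"s{i}" for i in range(3, 6)]}
        out = pca_projection(lc, "bulk", groups=groups)
        c_up = out["ellipses"]["up"]["center"][0]
        c_down = out["ellipses"]["down"]["center"][0]
        assert np.sign(c_up) != np.sign(c_down)
        # scores reproduce eigenvectors of the gene-space covariance
        X = lc.T.to_numpy()
        Xc = X - X.mean(axis=0)
        evals = np.linalg.eigvalsh(Xc @ Xc.T / (X.shape[0] - 1))[::-1]
        frac = evals[: len(out["variance_fraction"])] / evals.sum()
        assert np.allclose(
            sorted(out["variance_fraction"], reverse=True), frac[frac > 1e-12],
            atol=1e-8,
        )

    def test_gene_reordering_invariance(self):
        lc = self._log_counts()
        a = pca_projection(lc, "bulk")["scores"]
        b = pca_projection(lc.iloc[::-1], "bulk")["scores"]
        assert np.allclose(np.abs(a.to_numpy()), np.abs(b.to_numpy()), atol=1e-8)


class TestCompareGroups:
    def test_identical_paired(self):
        x = [1.0, 2.0, 3.0, 4.0]
        out = compare_groups(x, x, paired=True)
        assert out["estimate"] == 0.0
        assert out["p"] == 1.0

    def test_shift_recovery(self):
        rng = np.random.default_rng(9)
        b = rng.normal(0, 1, 10)
        out = compare_groups(b + 5, b, paired=True)
        assert out["estimate"] == pytest.approx(5.0, abs=1e-9)

    def test_disjoint_supports_minimal_p(self):
        a = [10.0, 11, 12, 13, 14]
        b = [0.0, 1, 2, 3, 4]
        out = compare_groups(a, b, paired=False)
        # exact two-sided rank-sum p for complete separation at n=m=5
        assert out["p"] == pytest.approx(2 / 252, rel=1e-6)
        assert out["significant"]
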