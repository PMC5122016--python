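import itertools

import numpy as np
import pandas as pd
import pytest

from scamp import detection_model as dm
from scamp.detection_model import (
    DetectionModelFit,
    TERM_NAMES,
    N_METHOD_TERMS,
    build_design_row,
    trim_covariates,
    fit_detection_glm,
    cooks_exclusion,
    goodness_of_fit,
    auc_bootstrap,
    predict_detection,
    fifty_percent_point,
    molecular_recovery_rate,
    odds_ratio,
    expected_gain_with_depth,
    squared_deviance_residuals,
    classify_detection_outliers,
    outlier_context_tests,
)


class FakeResult:
    """Stand-in fit result with chosen coefficients (identity covariance)."""

    def __init__(self, params):
        self.params = np.asarray(params, dtype=float)

    def cov_params(self):
        return np.eye(len(self.params)) * 1e-4


def make_fit(beta, methods=("m1",)):
    params = []
    names = []
    for m in methods:
        params.extend(beta[:N_METHOD_TERMS])
        names.extend(f"{m}:{t}" for t in TERM_NAMES[:N_METHOD_TERMS])
    params.append(beta[-1])
    names.append(TERM_NAMES[-1])
    return DetectionModelFit(
        result=FakeResult(params),
        methods=list(methods),
        column_names=names,
        covariate_medians={"L": 1.05, "G": 0.49, "S": -24.7, "A": 0.0, "D": 17.1},
        trim_bounds=None,
    )


class TestDesignRow:
    def test_molecule_terms_at_one(self):
        row = build_design_row(1.0, 1.0, 0.5, -20.0, 0, 10.0)
        assert row[TERM_NAMES.index("sqrt_M")] == 1.0
        assert row[TERM_NAMES.index("logM_sqrt_M")] == 0.0

    def test_gc_terms_at_one(self):
        row = build_design_row(2.0, 1.0, 1.0, -20.0, 0, 10.0)
        assert row[TERM_NAMES.index("G_inv2")] == 1.0
        assert row[TERM_NAMES.index("logG_G_inv2")] == 0.0

    def test_structure_shift_point(self):
        row = build_design_row(2.0, 1.0, 0.5, -39.1, 0, 10.0)
        assert row[TERM_NAMES.index("S_shifted")] == pytest.approx(0.0)

    @pytest.mark.parametrize("bad", [
        dict(M=0.0), dict(L=-1.0), dict(G=0.0), dict(G=1.5), dict(D=0.0),
    ])
    def test_domain_errors_name_covariate(self, bad):
        kwargs = dict(M=1.0, L=1.0, G=0.5, S=-20.0, A=0, D=10.0)
        kwargs.update(bad)
        with pytest.raises(ValueError, match=list(bad)[0]):
            build_design_row(**kwargs)


def _obs_frame(n_genes=200, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "gene_id": [f"g{i}" for i in range(n_genes)],
            "sample_id": "s0",
            "method": "m1",
            "Y": rng.integers(0, 2, n_genes),
            "M": rng.lognormal(1, 1, n_genes),
            "L": rng.lognormal(0, 0.5, n_genes),
            "G": rng.beta(10, 10, n_genes),
            "S": rng.normal(-25, 5, n_genes),
            "A": rng.integers(0, 2, n_genes),
            "D": 10.0,
        }
    )


class TestTrimCovariates:
    def test_identical_traits_nothing_removed(self):
        obs = _obs_frame(100)
        for t in ("M", "L", "G", "S"):
            obs[t] = 1.0 if t != "S" else -20.0
        out, _ = trim_covariates(obs)
        assert len(out) == len(obs)

    def test_single_trait_bounded_removal(self):
        obs = _obs_frame(1000)
        for t in ("L", "G", "S"):
            obs[t] = 0.5 if t != "S" else -20.0
        out, bounds = trim_covariates(obs)
        removed = len(obs) - len(out)
        assert 0 < removed <= 50
        assert bounds.loc["M", "lower"] < bounds.loc["M", "upper"]

    def test_union_of_per_trait_removals(self):
        obs = _obs_frame(200, seed=1)
        out, bounds = trim_covariates(obs)
        gene_traits = obs.groupby("gene_id")[["M", "L", "G", "S"]].mean()
        expected_kept = gene_traits.index[
            np.logical_and.reduce(
                [
                    gene_traits[t].between(*bounds.loc[t])
                    for t in ("M", "L", "G", "S")
                ]
            )
        ]
        assert set(out["gene_id"]) == set(expected_kept)


class TestFit:
    def test_coefficient_recovery_within_3se(self, logistic_fit):
        """Coefficients fitted to logistic-surface data land within three
        standard errors of the generating values."""
        fit, obs, beta_true = logistic_fit
        se = np.asarray(fit.result.bse)
        err = np.abs(np.asarray(fit.result.params) - beta_true)
        assert np.all(err < 3 * se)

    def test_duplication_invariance(self):
        obs = _obs_frame(300, seed=2)
        fit1 = fit_detection_glm(obs, holdout_fraction=0.0)
        fit2 = fit_detection_glm(
            pd.concat([obs, obs], ignore_index=True), holdout_fraction=0.0
        )
        assert np.allclose(fit1.result.params, fit2.result.params, atol=1e-6)

    def test_single_class_method_rejected(self):
        obs = _obs_frame(50)
        obs["Y"] = 1
        with pytest.raises(ValueError, match="detection class"):
            fit_detection_glm(obs)


class TestCooksRule:
    def _fit_two_methods(self):
        obs = pd.concat(
            [_obs_frame(60, seed=3).assign(method=m, sample_id=f"s_{m}")
             for m in ("m1", "m2")],
            ignore_index=True,
        )
        fit = fit_detection_glm(obs, holdout_fraction=0.0)
        return fit, obs

    def test_no_exceedance_empty(self):
        fit, obs = self._fit_two_methods()
        assert cooks_exclusion(fit, obs, cooks=np.zeros(len(obs))) == []

    def test_one_method_only_not_excluded(self):
        fit, obs = self._fit_two_methods()
        cooks = np.zeros(len(obs))
        idx = obs.index[(obs["gene_id"] == "g0") & (obs["method"] == "m1")]
        cooks[idx] = 0.01
        assert cooks_exclusion(fit, obs, cooks=cooks) == []

    def test_two_methods_excluded(self):
        fit, obs = self._fit_two_methods()
        obs = pd.concat([obs, obs], ignore_index=True)  # two obs per method
        cooks = np.zeros(len(obs))
        cooks[obs.index[obs["gene_id"] == "g0"]] = 0.01
        assert cooks_exclusion(fit, obs, cooks=cooks) == ["g0"]


class TestGoodnessOfFit:
    def test_order_invariance(self, logistic_fit):
        fit, _, _ = logistic_fit
        hold = fit.holdout
        shuffled = hold.sample(frac=1, random_state=0).reset_index(drop=True)
        a = goodness_of_fit(fit, hold)
        b = goodness_of_fit(fit, shuffled)
        assert a["chi_square"] == pytest.approx(b["chi_square"])
        assert a["sum_of_squares"] == pytest.approx(b["sum_of_squares"])

    def test_well_specified_near_null(self, logistic_fit):
        fit, _, _ = logistic_fit
        out = goodness_of_fit(fit)
        assert abs(out["chi_square_z"]) < 3
        assert abs(out["sum_of_squares_z"]) < 3

    def test_power_against_shifted_truth(self, logistic_fit):
        """Holdout generated from a shifted detection surface is flagged."""
        fit, obs, beta = logistic_fit
        rng = np.random.default_rng(0)
        hold = fit.holdout.copy()
        X, _ = dm.build_design_matrix(hold, fit.methods)
        p_shifted = 1 / (1 + np.exp(-(X @ beta + 1.5)))
        hold["Y"] = (rng.random(len(hold)) < p_shifted).astype(int)
        out = goodness_of_fit(fit, hold)
        assert abs(out["sum_of_squares_z"]) > 2


class TestAuc:
    def test_perfect_separation(self):
        y = np.array([0, 0, 1, 1], dtype=float)
        assert dm._auc(y, np.array([0.1, 0.2, 0.8, 0.9])) == 1.0

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, 2000).astype(float)
        auc = dm._auc(y, rng.random(2000))
        assert abs(auc - 0.5) < 0.05

    def test_exhaustive_pair_counting(self):
        rng = np.random.default_rng(2)
        y = rng.integers(0, 2, 30).astype(float)
        s = rng.random(30)
        brute = np.mean(
            [
                (1.0 if s[i] > s[j] else 0.5 if s[i] == s[j] else 0.0)
                for i, j in itertools.product(range(30), range(30))
                if y[i] == 1 and y[j] == 0
            ]
        )
        assert dm._auc(y, s) == pytest.approx(brute)

    def test_bootstrap_on_fit(self, logistic_fit):
        fit, _, _ = logistic_fit
        out = auc_bootstrap(fit, n_boot=200, seed=0)
        mean, sd = out["full_model"]
        assert 0.5 < mean <= 1.0
        assert 0 < sd < 0.1
        assert out["molecules_only"][0] <= mean + 0.02


class TestPredictAndSummaries:
    def test_all_zero_coefficients_give_half(self):
        fit = make_fit(np.zeros(9))
        assert predict_detection(fit, "m1", M=3.0) == pytest.approx(0.5)

    def test_monotone_in_molecules(self, logistic_fit):
        fit, _, _ = logistic_fit
        grid = np.linspace(0.2, 50, 100)
        p = predict_detection(fit, fit.methods[0], grid)
        assert np.all(np.diff(p) > 0)

    def test_unknown_method_rejected(self):
        fit = make_fit(np.zeros(9))
        with pytest.raises(KeyError):
            predict_detection(fit, "nope", M=1.0)

    def test_no_root_when_always_above_half(self):
        beta = np.zeros(9)
        beta[0] = 3.0  # p > 0.95 everywhere
        fit = make_fit(beta)
        with pytest.raises(ValueError, match="cross"):
            fifty_percent_point(fit, "m1")

    def test_recovery_rate_identities(self):
        beta = np.zeros(9)
        fit = make_fit(beta)
        # p(1) = 0.5 -> rate = 0.5 / (1 - 1/e)
        assert molecular_recovery_rate(fit, "m1") == pytest.approx(
            0.5 / (1 - np.exp(-1))
        )


class TestOddsRatio:
    def test_zero_coefficient_gives_unity(self):
        fit = make_fit(np.zeros(9))
        out = odds_ratio(fit, "m1", "L", 0.681, 2.40)
        assert out["odds_ratio"] == pytest.approx(1.0)

    def test_from_equals_to(self, logistic_fit):
        fit, _, _ = logistic_fit
        out = odds_ratio(fit, fit.methods[0], "S", -24.7, -24.7)
        assert out["odds_ratio"] == pytest.approx(1.0)

    def test_hexamer_or_is_exp_beta7(self, logistic_fit):
        fit, _, _ = logistic_fit
        m = fit.methods[0]
        beta7 = fit.params[f"{m}:A"]
        out = odds_ratio(fit, m, "A", 0, 1)
        assert out["odds_ratio"] == pytest.approx(np.exp(beta7))

    def test_method_comparison_bonferroni(self, logistic_fit):
        fit, _, _ = logistic_fit
        # single-method fit -> no pairs
        out = dm.compare_method_effects(fit, "L", 0.681, 2.40)
        assert len(out) == 0


class TestDepthGain:
    def test_equal_depths_zero(self, logistic_fit):
        fit, obs, _ = logistic_fit
        assert expected_gain_with_depth(fit, obs, 10, 10) == 0.0

    def test_zero_depth_coefficient_zero_gain(self):
        fit = make_fit(np.array([0.5, 1, 0, 0, 0, 0, 0, 0, 0.0]))
        obs = _obs_frame(100)
        assert expected_gain_with_depth(fit, obs, 10, 15) == pytest.approx(0.0)

    def test_direct_summation_oracle(self, logistic_fit):
        fit, obs, _ = logistic_fit
        sub = obs.iloc[:100]
        gain = expected_gain_with_depth(fit, sub, 10, 15)
        m = fit.methods[0]
        p_from = sum(
            predict_detection(fit, m, r.M, r.L, r.G, r.S, r.A, 10.0)
            for r in sub.itertuples()
        )
        p_to = sum(
            predict_detection(fit, m, r.M, r.L, r.G, r.S, r.A, 15.0)
            for r in sub.itertuples()
        )
        assert gain == pytest.approx(100 * (p_to - p_from) / p_from)


class TestDevianceResiduals:
    @pytest.mark.parametrize(
        "y,p,expected",
        [(1, 1.0, 0.0), (1, 0.5, 2 * np.log(2)), (1, np.exp(-2), 4.0),
         (0, 0.5, 2 * np.log(2))],
    )
    def test_closed_forms(self, y, p, expected):
        assert squared_deviance_residuals([y], [p])[0] == pytest.approx(expected)

    def test_sum_equals_model_deviance(self, logistic_fit):
        fit, _, _ = logistic_fit
        X, _ = dm.build_design_matrix(fit.train, fit.methods)
        p = 1 / (1 + np.exp(-(X @ np.asarray(fit.result.params))))
        d2 = squared_deviance_residuals(fit.train["Y"], p)
        assert d2.sum() == pytest.approx(fit.result.deviance, rel=1e-8)

    def test_infinite_residual_flagged(self):
        d2 = squared_deviance_residuals([1], [0.0])
        assert np.isinf(d2[0])


class TestOutlierCatalog:
    def test_no_outliers_below_threshold(self):
        obs = _obs_frame(50)
        out = classify_detection_outliers(obs, np.full(len(obs), 3.9))
        assert out.empty

    def test_boundary_is_strict(self):
        obs = _obs_frame(50)
        out = classify_detection_outliers(obs, np.full(len(obs), 4.0))
        assert out.empty

    def test_labels_follow_majority_state(self):
        obs = pd.DataFrame(
            {
                "gene_id": ["g"] * 3 + ["h"] * 3 + ["t"] * 2,
                "method": "m1",
                "Y": [1, 1, 0, 0, 0, 1, 0, 1],
            }
        )
        d2 = np.full(8, 5.0)
        out = classify_detection_outliers(obs, d2).set_index("gene_id")
        assert out.loc["g", "label"] == "detected"
        assert out.loc["h", "label"] == "undetected"
        assert out.loc["t", "label"] == "mixed"


class TestOutlierContext:
    def _traits(self, shift=0.0, n=40, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            {
                "mappability_fraction": np.clip(rng.beta(5, 2, n) - shift, 0, 1),
                "overlap_fraction": np.clip(rng.beta(2, 5, n) + shift, 0, 1),
            }
        )

    def test_shifted_outliers_significant(self):
        out = outlier_context_tests(self._traits(shift=0.4, seed=1), self._traits(seed=2))
        assert (out["p"] < 0.05).all()

    def test_rank_invariance_under_monotone_transform(self):
        a, b = self._traits(seed=3), self._traits(seed=4)
        r1 = outlier_context_tests(a, b)
        r2 = outlier_context_tests(a**3, b**3)
        assert np.allclose(r1["p"], r2["p"])

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            outlier_context_tests(self._traits(n=1), self._traits())
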