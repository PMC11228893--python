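"""Standardized association fits, screens, inflation factor, MR, trend summaries."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ribocn.association import (
    ModelSpec,
    effect_profile_correlation,
    fit_association,
    genomic_inflation,
    group_difference_test,
    ivw_mr,
    phenome_screen,
    quantile_trend,
    se_from_beta_p,
)
from ribocn.errors import InsufficientDataError, ModelError, ValidationError


class TestFitAssociation:
    def test_perfect_proportionality_standardizes_to_unit_beta(self, rng):
        x = rng.normal(size=200)
        table = pd.DataFrame({"x": x, "y": 2 * x})
        res = fit_association(table, ModelSpec("y", "x"))
        assert res.beta == pytest.approx(1.0)
        assert res.p < 1e-100

    def test_standardized_simple_beta_equals_pearson_r(self, rng):
        x = rng.normal(size=500)
        y = 0.3 * x + rng.normal(size=500)
        table = pd.DataFrame({"x": x, "y": y})
        res = fit_association(table, ModelSpec("y", "x"))
        r, _ = stats.pearsonr(x, y)
        assert res.beta == pytest.approx(r, abs=1e-10)

    def test_null_p_uniformity(self, rng):
        pvals = []
        for _ in range(200):
            table = pd.DataFrame({"x": rng.normal(size=400), "y": rng.normal(size=400)})
            pvals.append(fit_association(table, ModelSpec("y", "x")).p)
        # Kolmogorov-Smirnov against Uniform(0,1)
        _, ks_p = stats.kstest(pvals, "uniform")
        assert ks_p > 1e-3

    def test_logistic_recovers_known_log_odds(self, rng):
        n = 40_000
        x = rng.normal(size=n)
        logit = -2.4 + 0.0392 * x
        y = rng.binomial(1, 1 / (1 + np.exp(-logit)))
        table = pd.DataFrame({"x": x, "y": y})
        res = fit_association(table, ModelSpec("y", "x", family="logistic"))
        assert res.ci_low <= 0.0392 <= res.ci_high
        assert res.or_value == pytest.approx(math.exp(res.beta))

    def test_categorical_covariate_absorbs_batch_shift(self, rng):
        n = 2_000
        center = rng.choice(["A", "B"], n)
        x = rng.normal(size=n) + (center == "B") * 2.0
        y = 0.2 * rng.normal(size=n) + (center == "B") * 1.0
        table = pd.DataFrame({"x": x, "y": y, "center": center})
        biased = fit_association(table, ModelSpec("y", "x"))
        adjusted = fit_association(
            table, ModelSpec("y", "x", covariates=["center"], categorical=["center"])
        )
        assert abs(adjusted.beta) < abs(biased.beta)

    def test_nonbinary_logistic_response_rejected(self, rng):
        table = pd.DataFrame({"x": rng.normal(size=50), "y": rng.integers(0, 3, 50)})
        with pytest.raises(ValidationError):
            fit_association(table, ModelSpec("y", "x", family="logistic"))

    def test_rank_deficiency_names_a_column(self, rng):
        x = rng.normal(size=100)
        table = pd.DataFrame({"x": x, "copy": x, "y": rng.normal(size=100)})
        with pytest.raises(ModelError):
            fit_association(table, ModelSpec("y", "x", covariates=["copy"]))

    def test_exposure_as_covariate_rejected(self):
        with pytest.raises(ValidationError):
            ModelSpec("y", "x", covariates=["x"])


class TestPhenomeScreen:
    def _cohort(self, rng, n=3_000, n_null=20, planted=None):
        cn = rng.normal(size=n)
        cols = {"cn": cn}
        phenos = {}
        for i in range(n_null):
            cols[f"null{i}"] = rng.normal(size=n)
            phenos[f"null{i}"] = "continuous"
        for name, beta in (planted or {}).items():
            cols[name] = beta * cn + rng.normal(size=n)
            phenos[name] = "continuous"
        return pd.DataFrame(cols), phenos

    def test_planted_effects_discovered_nulls_not(self, rng):
        table, phenos = self._cohort(rng, planted={"hit1": 0.5, "hit2": -0.4})
        out = phenome_screen(table, "cn", phenos).set_index("phenotype")
        assert out.loc["hit1", "fdr"] < 0.01
        assert out.loc["hit2", "fdr"] < 0.01
        assert (out.drop(["hit1", "hit2"])["fdr"] > 0.01).all()

    def test_min_cases_exclusion_reason(self, rng):
        table, phenos = self._cohort(rng, n=1_000)
        table["rare"] = (rng.uniform(size=1_000) < 0.05).astype(int)  # ~50 cases
        phenos["rare"] = "binary"
        out = phenome_screen(table, "cn", phenos).set_index("phenotype")
        assert out.loc["rare", "excluded"] == "min_cases"

    def test_min_measured_fraction_exclusion(self, rng):
        table, phenos = self._cohort(rng, n=1_000)
        sparse = pd.Series(np.nan, index=table.index)
        sparse.iloc[:100] = rng.normal(size=100)
        table["sparse"] = sparse
        phenos["sparse"] = "continuous"
        out = phenome_screen(table, "cn", phenos).set_index("phenotype")
        assert out.loc["sparse", "excluded"] == "min_measured_fraction"

    def test_fdr_over_eligible_set_only(self, rng):
        table, phenos = self._cohort(rng, n=1_000)
        table["rare"] = 0
        phenos["rare"] = "binary"
        out = phenome_screen(table, "cn", phenos)
        assert out.loc[out["excluded"].notna(), "fdr"].isna().all()


class TestGenomicInflation:
    def test_all_half_is_exactly_one(self):
        assert genomic_inflation([0.5] * 100) == pytest.approx(1.0)

    def test_single_p_chi_square_quantile_ratio(self):
        # chi2 quantile at 1-0.05 over the null median 0.4549
        assert genomic_inflation([0.05]) == pytest.approx(3.8415 / 0.4549, abs=2e-3)

    def test_uniform_null_converges_to_one(self, rng):
        lam = genomic_inflation(rng.uniform(size=200_000))
        assert lam == pytest.approx(1.0, abs=0.02)

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValidationError):
            genomic_inflation([])
        with pytest.raises(ValidationError):
            genomic_inflation([0.0, 0.5])
        with pytest.raises(ValidationError):
            genomic_inflation([1.5])


class TestSeFromBetaP:
    def test_known_value(self):
        assert se_from_beta_p(1.0, 0.05) == pytest.approx(1 / 1.95996, abs=1e-4)

    def test_sign_invariance(self):
        assert se_from_beta_p(-2.0, 0.05) == pytest.approx(2 * se_from_beta_p(1.0, 0.05))

    def test_round_trip_p(self):
        beta, p = 0.37, 0.0123
        se = se_from_beta_p(beta, p)
        recovered = 2 * stats.norm.sf(abs(beta) / se)
        assert recovered == pytest.approx(p, rel=1e-9)

    @pytest.mark.parametrize("p", [0.0, 1.0, -0.1])
    def test_degenerate_p_rejected(self, p):
        with pytest.raises(ValidationError):
            se_from_beta_p(1.0, p)


class TestIVW:
    def test_single_instrument_wald_ratio(self):
        beta, se, _ = ivw_mr([0.5], [0.25], [0.1])
        assert beta == pytest.approx(0.25 / 0.5)
        assert se == pytest.approx(0.1 / 0.5)

    def test_equal_weight_mean_of_ratios(self):
        # equal bx and se_y: estimate is the mean of the two Wald ratios
        beta, _, _ = ivw_mr([0.5, 0.5], [0.2, 0.3], [0.1, 0.1])
        assert beta == pytest.approx((0.4 + 0.6) / 2)

    def test_zero_weight_instrument_leaves_estimate_unchanged(self):
        b1, s1, _ = ivw_mr([0.5, 0.4], [0.2, 0.1], [0.1, 0.2])
        b2, s2, _ = ivw_mr([0.5, 0.4, 0.0], [0.2, 0.1, 5.0], [0.1, 0.2, 0.3])
        assert b2 == pytest.approx(b1)
        assert s2 == pytest.approx(s1)

    def test_recovers_simulated_causal_effect(self, rng):
        true_effect = 0.3
        n_inst = 50
        bx = rng.uniform(0.05, 0.3, n_inst)
        se_y = np.full(n_inst, 0.02)
        by = true_effect * bx + rng.normal(0, se_y)
        beta, se, p = ivw_mr(bx, by, se_y)
        assert abs(beta - true_effect) < 2 * se
        assert p < 0.05

    def test_no_instruments_rejected(self):
        with pytest.raises(ValidationError):
            ivw_mr([], [], [])


class TestEffectProfiles:
    def test_identical_profiles_unit_correlation(self, rng):
        a = pd.DataFrame({"beta": rng.normal(size=30), "fdr": 0.001},
                         index=[f"prot{i}" for i in range(30)])
        r, _, n = effect_profile_correlation(a, a)
        assert r == pytest.approx(1.0)
        assert n == 30

    def test_independent_profiles_near_zero(self, rng):
        idx = [f"prot{i}" for i in range(500)]
        a = pd.DataFrame({"beta": rng.normal(size=500), "fdr": 0.001}, index=idx)
        b = pd.DataFrame({"beta": rng.normal(size=500)}, index=idx)
        r, _, _ = effect_profile_correlation(a, b)
        assert abs(r) < 0.15

    def test_too_few_significant_features_raise(self, rng):
        idx = ["p1", "p2", "p3"]
        a = pd.DataFrame({"beta": [1.0, 2.0, 3.0], "fdr": [0.5, 0.5, 0.001]}, index=idx)
        b = pd.DataFrame({"beta": [1.0, 2.0, 3.0]}, index=idx)
        with pytest.raises(InsufficientDataError):
            effect_profile_correlation(a, b)


class TestQuantileTrend:
    def test_equal_count_bins(self, rng):
        table = pd.DataFrame({"g": rng.permutation(100).astype(float),
                              "y": rng.normal(size=100)})
        out = quantile_trend(table, "g", "y")
        assert list(out["n"]) == [20] * 5
        assert list(out["group"]) == ["Low", "Mid-Low", "Mid", "Mid-High", "High"]

    def test_monotone_outcome_gives_increasing_means(self, rng):
        v = rng.normal(size=200)
        table = pd.DataFrame({"g": v, "y": v})
        out = quantile_trend(table, "g", "y")
        assert out["mean"].is_monotonic_increasing

    def test_ci_half_width_uses_t_quantile(self, rng):
        table = pd.DataFrame({"g": np.arange(150.0), "y": rng.normal(size=150)})
        out = quantile_trend(table, "g", "y")
        row = out.iloc[0]
        vals = table["y"][table["g"] < 30]
        expected = stats.t.ppf(0.975, 29) * vals.std(ddof=1) / math.sqrt(30)
        assert (row["ci_high"] - row["mean"]) == pytest.approx(expected)

    def test_heavy_ties_raise(self):
        table = pd.DataFrame({"g": [1.0] * 50, "y": np.arange(50.0)})
        with pytest.raises(ValidationError):
            quantile_trend(table, "g", "y")


class TestGroupDifference:
    def test_identical_paired_samples_degenerate(self):
        with pytest.raises(ValidationError):
            group_difference_test([1, 2, 3], [1, 2, 3], paired=True)

    def test_location_shift_detected(self, rng):
        a = rng.normal(0, 1, 500)
        b = rng.normal(1, 1, 500)
        _, p = group_difference_test(a, b)
        assert p < 1e-10

    def test_matches_scipy_reference_on_random_data(self, rng):
        for _ in range(20):
            a = rng.normal(size=30)
            b = rng.normal(size=25)
            stat, p = group_difference_test(a, b)
            ref_stat, ref_p = stats.mannwhitneyu(a, b, alternative="two-sided")
            assert stat == ref_stat and p == ref_p
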