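import numpy as np
import pandas as pd
import pytest
from scipy import stats

from neohrv.errors import InsufficientDataError, ValidationError
from neohrv.robustness import (
    bias_loa,
    boxcox_transform,
    lme_length_effect,
    mad_profile,
    significance_stars,
    summarize_distribution,
)

from conftest import make_feature_table
from oracles import mad_bruteforce


class TestDistributionSummary:
    def test_quantiles_1_to_100(self):
        med, q1, q3, w, p = summarize_distribution(np.arange(1.0, 101.0))
        assert (med, q1, q3) == (50.5, 25.75, 75.25)

    def test_shapiro_p_uniform_under_null(self):
        ps = []
        for seed in range(200):
            x = np.random.default_rng(seed).standard_normal(500)
            ps.append(summarize_distribution(x)[4])
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_shapiro_rejects_lognormal(self):
        x = np.exp(np.random.default_rng(0).standard_normal(500))
        assert summarize_distribution(x)[4] < 1e-3

    def test_too_few_values(self):
        with pytest.raises(InsufficientDataError):
            summarize_distribution([1.0, 2.0])


class TestMAD:
    def test_direct_arithmetic_example(self):
        tab = make_feature_table(0, n_subjects=1, n_recordings=1)
        tab = tab[tab.length_class == "S5"].copy()
        tab["value"] = [1.0, 1.0, 2.0, 2.0, 4.0]
        out = mad_profile(tab)
        assert out["mad"].iloc[0] == 1.0

    def test_constant_cell_zero(self):
        tab = make_feature_table(0, n_subjects=2, window_sd=0.0,
                                 subject_sd=0.0, recording_sd=0.0)
        out = mad_profile(tab)
        assert np.allclose(out["mad"], 0.0)

    def test_matches_bruteforce_per_cell(self):
        tab = make_feature_table(3, n_subjects=10)
        out = mad_profile(tab)
        for _, row in out.iterrows():
            cell = tab[
                (tab.feature == row.feature)
                & (tab.length_class == row.length_class)
                & (tab.pma_class == row.pma_class)
            ]["value"]
            assert row["mad"] == pytest.approx(mad_bruteforce(cell), abs=1e-12)
            assert row["n"] == len(cell)

    def test_shift_invariance_and_positive_scaling(self):
        tab = make_feature_table(4, n_subjects=8)
        base = mad_profile(tab).set_index(["length_class", "pma_class"])["mad"]
        shifted = tab.copy()
        shifted["value"] += 123.0
        scaled = tab.copy()
        scaled["value"] *= 2.5
        s1 = mad_profile(shifted).set_index(["length_class", "pma_class"])["mad"]
        s2 = mad_profile(scaled).set_index(["length_class", "pma_class"])["mad"]
        assert np.allclose(base, s1)
        assert np.allclose(2.5 * base, s2)


class TestBoxCox:
    def test_lambda_one_is_shifted_identity(self):
        v = np.array([1.0, 2.0, 5.0])
        lams = np.linspace(-3, 3, 601)
        assert 1.0 in lams  # grid contains the identity
        t, _ = boxcox_transform(v)
        # direct check of the transform formula at lambda = 1
        assert np.allclose(stats.boxcox(v, lmbda=1.0), v - 1.0)

    def test_lognormal_lambda_near_zero(self):
        v = np.exp(np.random.default_rng(1).standard_normal(1000))
        _, lam = boxcox_transform(v)
        assert abs(lam) < 0.15

    def test_gaussian_lambda_near_one(self):
        v = np.random.default_rng(2).normal(10.0, 1.0, 1000)
        _, lam = boxcox_transform(v)
        assert abs(lam - 1.0) < 0.5

    def test_nonpositive_rejected(self):
        with pytest.raises(ValidationError):
            boxcox_transform([1.0, 0.0, 2.0])


class TestLengthEffectModel:
    def test_single_subject_rejected(self):
        tab = make_feature_table(0, n_subjects=1)
        with pytest.raises(InsufficientDataError):
            lme_length_effect(tab, "f")

    def test_recovers_injected_us_shift(self):
        tab = make_feature_table(1, n_subjects=40, us_shift=-2.0)
        res = lme_length_effect(tab, "f", transform="never")
        term = [t for t in res.params.index if "US" in t][0]
        est, halfwidth = res.params[term], 1.96 * res.bse[term]
        assert est - halfwidth <= -2.0 <= est + halfwidth
        assert res.lrt_p < 1e-6
        assert res.var_subject > 0

    def test_no_effect_gives_large_p(self):
        tab = make_feature_table(2, n_subjects=30)
        res = lme_length_effect(tab, "f", transform="never")
        assert res.lrt_p > 0.001  # no systematic length effect injected

    def test_skewed_response_triggers_boxcox(self):
        tab = make_feature_table(3, n_subjects=30)
        tab["value"] = np.exp(tab["value"] / 5.0)
        res = lme_length_effect(tab, "f", transform="auto")
        assert res.boxcox_lambda is not None


class TestBiasLoA:
    def test_identical_values_collapse_to_zero(self):
        tab = make_feature_table(
            0, n_subjects=10, subject_sd=0.0, recording_sd=0.0, window_sd=0.0
        )
        out = bias_loa(tab, "f")
        assert np.allclose(out["bias_pct"], 0.0, atol=1e-8)
        assert np.allclose(out["loa_low_pct"], 0.0, atol=1e-6)
        assert np.allclose(out["loa_high_pct"], 0.0, atol=1e-6)

    def test_biases_sum_to_zero_with_mean_reference(self):
        tab = make_feature_table(5, n_subjects=40)
        out = bias_loa(tab, "f", reference="mean")
        assert out["bias_pct"].sum() == pytest.approx(0.0, abs=0.5)
        assert (out["loa_low_pct"] <= out["bias_pct"]).all()
        assert (out["bias_pct"] <= out["loa_high_pct"]).all()

    def test_invalid_reference_rejected(self):
        with pytest.raises(ValidationError):
            bias_loa(make_feature_table(0, n_subjects=3), "f", reference="gold")


def test_significance_stars_levels():
    assert significance_stars(0.2) == ""
    assert significance_stars(0.04) == "*"
    assert significance_stars(0.004) == "**"
    assert significance_stars(4e-4) == "***"
    assert significance_stars(4e-5) == "****"
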