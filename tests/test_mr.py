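"""Estimator correctness against closed forms and independent oracles."""

import math

import numpy as np
import pytest
import statsmodels.api as sm

from mrmediation import (
    InsufficientInstrumentsError,
    SimConfig,
    UndefinedRatioError,
    cochran_q,
    egger,
    ivw,
    simulate_tri_trait,
    to_or,
    wald_ratio,
)

from conftest import make_harmonized


class TestWaldRatio:
    def test_first_order_arithmetic(self):
        est = wald_ratio({"beta_exp": 0.1, "se_exp": 0.01,
                          "beta_out": 0.2, "se_out": 0.05})
        assert est.beta == pytest.approx(2.0)
        assert est.se == pytest.approx(0.5)

    def test_null_outcome_gives_p_one(self):
        est = wald_ratio({"beta_exp": 0.1, "se_exp": 0.01,
                          "beta_out": 0.0, "se_out": 0.05})
        assert est.beta == 0.0 and est.pval == 1.0

    def test_zero_exposure_effect_raises(self):
        with pytest.raises(UndefinedRatioError):
            wald_ratio({"beta_exp": 0.0, "se_exp": 0.01,
                        "beta_out": 0.1, "se_out": 0.05})

    def test_second_order_delta_closed_form(self):
        r = {"beta_exp": 0.1, "se_exp": 0.02, "beta_out": 0.05, "se_out": 0.03}
        first = wald_ratio(r)
        second = wald_ratio(r, second_order=True)
        assert first.se == pytest.approx(0.3)
        expected = math.sqrt(0.03 ** 2 / 0.1 ** 2 + 0.05 ** 2 * 0.02 ** 2 / 0.1 ** 4)
        assert second.se == pytest.approx(expected)
        assert second.se == pytest.approx(0.31623, abs=5e-6)

    def test_second_order_delta_vs_monte_carlo(self):
        # the ratio of normals has no finite moments (Cauchy-like tails), so
        # the sampling spread is measured by the central 68% interval, which
        # equals the SD for the near-Gaussian bulk the delta method models
        r = {"beta_exp": 0.1, "se_exp": 0.02, "beta_out": 0.05, "se_out": 0.03}
        rng = np.random.default_rng(12345)
        draws = rng.normal(0.05, 0.03, 10 ** 6) / rng.normal(0.1, 0.02, 10 ** 6)
        lo, hi = np.percentile(draws, [15.865, 84.135])
        mc_spread = (hi - lo) / 2.0
        assert wald_ratio(r, second_order=True).se == pytest.approx(mc_spread, rel=0.05)


class TestIVW:
    def test_single_snp_degenerates_to_wald(self):
        h = make_harmonized([0.1], [0.01], [0.2], [0.05])
        est = ivw(h)
        ref = wald_ratio(h.df.iloc[0])
        assert (est.beta, est.se, est.pval, est.n_snp) == \
            (ref.beta, ref.se, ref.pval, 1)

    def test_homogeneous_two_snp_closed_form(self):
        # ratios both 1.0 with sigma 0.1 and 0.2 -> beta 1, Q 0, fe se sqrt(1/125)
        h = make_harmonized([1.0, 1.0], 0.01, [1.0, 1.0], [0.1, 0.2])
        fe = ivw(h, model="fe")
        assert fe.beta == pytest.approx(1.0)
        assert fe.se == pytest.approx(math.sqrt(1 / 125.0))
        assert fe.se == pytest.approx(0.08944, abs=5e-6)
        mre = ivw(h, model="mre")
        assert mre.se == fe.se  # Q = 0 -> no inflation

    def test_matches_weighted_normal_equations_oracle(self, harmonized_20):
        est = ivw(harmonized_20, model="fe")
        df = harmonized_20.df
        w = df["se_out"] ** -2
        fit = sm.WLS(df["beta_out"], df["beta_exp"], weights=w).fit()
        assert est.beta == pytest.approx(fit.params.iloc[0], abs=1e-10)

    def test_mre_never_narrower_than_fe(self, harmonized_20):
        assert ivw(harmonized_20, "mre").se >= ivw(harmonized_20, "fe").se

    def test_invariant_to_order_and_joint_sign_flips(self, harmonized_20):
        est = ivw(harmonized_20)
        df = harmonized_20.df.sample(frac=1, random_state=1).reset_index(drop=True)
        df.loc[::2, ["beta_exp", "beta_out"]] *= -1
        flipped = make_harmonized(df["beta_exp"], df["se_exp"],
                                  df["beta_out"], df["se_out"])
        est2 = ivw(flipped)
        assert est2.beta == pytest.approx(est.beta, abs=1e-12)
        assert est2.se == pytest.approx(est.se, abs=1e-12)

    def test_zero_exposure_snps_excluded_with_warning(self, caplog):
        h = make_harmonized([0.1, 0.0], 0.01, [0.2, 0.3], 0.05)
        with caplog.at_level("WARNING"):
            est = ivw(h)
        assert est.n_snp == 1
        assert any("zero exposure effect" in r.message for r in caplog.records)

    def test_all_zero_exposure_raises(self):
        h = make_harmonized([0.0, 0.0], 0.01, [0.2, 0.3], 0.05)
        with pytest.raises(UndefinedRatioError):
            ivw(h)


class TestCochranQ:
    def test_homogeneity_gives_zero(self):
        h = make_harmonized([0.1, 0.2, 0.4], 0.01, [0.05, 0.1, 0.2], 0.05)
        het = cochran_q(h, ivw(h, "fe").beta)
        assert het.q == pytest.approx(0.0, abs=1e-20)
        assert het.i2 == 0.0 and het.pval == pytest.approx(1.0)

    def test_hand_arithmetic_two_snps(self):
        # ratios 1 and 3, both sigma 1, pooled 2 -> Q = 2, df = 1
        h = make_harmonized([1.0, 1.0], 0.01, [1.0, 3.0], 1.0)
        het = cochran_q(h, 2.0)
        assert het.q == pytest.approx(2.0) and het.df == 1

    def test_direct_summation_oracle(self):
        rng = np.random.default_rng(3)
        be = rng.normal(0.05, 0.01, 30)
        bo = 0.3 * be + rng.normal(0, 0.03, 30)
        so = rng.uniform(0.01, 0.05, 30)
        h = make_harmonized(be, 0.004, bo, so)
        pooled = ivw(h, "fe").beta
        het = cochran_q(h, pooled)
        q_oracle = 0.0
        for j in range(30):
            theta_j = bo[j] / be[j]
            w_j = (abs(be[j]) / so[j]) ** 2
            q_oracle += w_j * (theta_j - pooled) ** 2
        assert het.q == pytest.approx(q_oracle, abs=1e-10)

    def test_single_snp_raises(self):
        h = make_harmonized([0.1], 0.01, [0.2], 0.05)
        with pytest.raises(InsufficientInstrumentsError):
            cochran_q(h, 2.0)


class TestEgger:
    def test_exact_line_recovered(self):
        be = np.array([0.1, 0.2, 0.3, 0.4])
        bo = 0.05 + 0.3 * be
        h = make_harmonized(be, 0.01, bo, 0.05)
        res = egger(h)
        assert res.slope.beta == pytest.approx(0.3, abs=1e-12)
        assert res.intercept == pytest.approx(0.05, abs=1e-12)

    def test_orientation_invariance(self, harmonized_20):
        ref = egger(harmonized_20)
        df = harmonized_20.df.copy()
        df.loc[[0, 3, 7], ["beta_exp", "beta_out"]] *= -1
        res = egger(make_harmonized(df["beta_exp"], df["se_exp"],
                                    df["beta_out"], df["se_out"]))
        assert res.slope.beta == pytest.approx(ref.slope.beta, abs=1e-12)
        assert res.intercept == pytest.approx(ref.intercept, abs=1e-12)

    def test_matches_wls_oracle(self, harmonized_20):
        res = egger(harmonized_20)
        df = harmonized_20.df
        sign = np.sign(df["beta_exp"])
        x = sm.add_constant(df["beta_exp"] * sign)
        fit = sm.WLS(df["beta_out"] * sign, x, weights=df["se_out"] ** -2).fit()
        assert res.intercept == pytest.approx(fit.params.iloc[0], abs=1e-10)
        assert res.slope.beta == pytest.approx(fit.params.iloc[1], abs=1e-10)

    def test_insufficient_instruments(self):
        h = make_harmonized([0.1, 0.2], 0.01, [0.1, 0.2], 0.05)
        with pytest.raises(InsufficientInstrumentsError):
            egger(h)

    def test_null_intercept_coverage_on_clean_simulations(self):
        # strong instruments, no pleiotropy: the pleiotropy intercept should
        # cover zero at its nominal rate
        hits = 0
        n_rep = 200
        for seed in range(n_rep):
            cfg = SimConfig(m_snps=30, m_snps_med=0, gamma_sd=0.05, seed=seed)
            x, _, y, t, _ = simulate_tri_trait(cfg)
            h = make_harmonized(x.df["beta"], x.df["se"], y.df["beta"], y.df["se"])
            res = egger(h)
            if abs(res.intercept) <= 2 * res.intercept_se:
                hits += 1
        assert hits / n_rep >= 0.93


class TestOrFormatting:
    def test_printed_total_effect_reproduces_published_or(self):
        # log-odds -2.175 for a sleep-trait/cluster-headache pair
        from mrmediation.mr import MREstimate
        est = MREstimate("ivw_mre", -2.175, 1.0, 0.04, 10)
        or_s, _ = to_or(est)
        assert or_s == "0.114"

    def test_null_effect_symmetric_ci(self):
        from mrmediation.mr import MREstimate
        est = MREstimate("ivw_mre", 0.0, 0.1, 1.0, 5)
        or_s, _ = to_or(est)
        assert or_s == "1.000"
        assert math.log(est.ci_low) == pytest.approx(-math.log(est.ci_high), abs=1e-12)

    def test_ci_reconstruction_from_printed_values(self):
        # beta/se back-computed from a published OR with CI 1.15-3.697;
        # agreement with the printed interval only up to print rounding
        from mrmediation.mr import MREstimate
        est = MREstimate("ivw_mre", 0.7262, 0.2979, 0.014, 20)
        assert est.ci_low == pytest.approx(1.152, rel=0.01)
        assert est.ci_high == pytest.approx(3.707, rel=0.01)
        assert est.ci_low == pytest.approx(1.15, rel=0.01)
        assert est.ci_high == pytest.approx(3.697, rel=0.01)
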