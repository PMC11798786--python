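import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mrmediate.mr import (
    EstimatorError,
    all_estimates,
    cochran_q,
    egger,
    ivw,
    leave_one_out,
    mode_estimate,
    per_snp_wald_ratios,
    sensitivity_report,
    to_odds_ratio,
    wald_ratio,
    weighted_median,
)
from mrmediate.sumstats import harmonize
from mrmediate.synthgwas import SimulationConfig, simulate_study
from tests.conftest import make_hset


class TestWaldRatio:
    def test_ratio_arithmetic(self):
        est = wald_ratio(0.1, 0.01, 0.02, 0.005)
        assert est.beta == pytest.approx(0.2)
        assert est.se == pytest.approx(0.05)

    def test_unit_denominator(self):
        est = wald_ratio(1.0, 0.01, 0.1515, 0.01)
        assert est.beta == pytest.approx(0.1515)

    def test_sign_tracks_ratio(self):
        est = wald_ratio(-0.1, 0.01, 0.02, 0.005)
        assert est.beta == pytest.approx(-0.2)
        assert est.se == pytest.approx(0.05)  # |gamma| in the denominator

    def test_null_instrument_errors(self):
        with pytest.raises(EstimatorError, match="null instrument"):
            wald_ratio(0.0, 0.01, 0.02, 0.005)

    def test_second_order_se_larger(self):
        first = wald_ratio(0.1, 0.05, 0.02, 0.005)
        second = wald_ratio(0.1, 0.05, 0.02, 0.005, second_order=True)
        assert second.se > first.se
        expected = np.sqrt(0.005**2 / 0.01 + 0.02**2 * 0.05**2 / 0.1**4)
        assert second.se == pytest.approx(expected)


class TestIVW:
    def test_single_snp_reduces_to_wald(self):
        h = make_hset([0.1], [0.02], se_big_gamma=0.005)
        est = ivw(h)
        ref = wald_ratio(0.1, 0.01, 0.02, 0.005)
        assert est.beta == pytest.approx(ref.beta)
        assert est.se == pytest.approx(ref.se)
        assert est.method == "ivw"

    def test_two_snp_hand_computation(self):
        # weights gamma^2/se_G^2 = 100, 400; ratios 0.2, 0.15
        h = make_hset([0.1, 0.2], [0.02, 0.03], se_big_gamma=0.01)
        est = ivw(h, variance_mode="fixed")
        assert est.beta == pytest.approx((100 * 0.2 + 400 * 0.15) / 500)
        assert est.se == pytest.approx(1 / np.sqrt(500))

    def test_matches_generic_wls_oracle(self):
        """DERIVED: IVW equals weighted regression through the origin
        of big_gamma on gamma with weights 1/se^2 (normal equations)."""
        rng = np.random.default_rng(0)
        g = rng.normal(0.1, 0.05, 15)
        G = 0.2 * g + rng.normal(0, 0.01, 15)
        se_G = rng.uniform(0.005, 0.02, 15)
        h = make_hset(g, G, se_big_gamma=se_G)
        est = ivw(h, variance_mode="fixed")
        w = 1 / se_G**2
        beta_wls = np.sum(w * g * G) / np.sum(w * g**2)
        assert est.beta == pytest.approx(beta_wls, rel=1e-12)

    def test_multiplicative_random_floor(self):
        # perfectly homogeneous ratios: Q = 0 -> floor keeps fixed SE
        h = make_hset([0.1, 0.2, 0.3], [0.02, 0.04, 0.06])
        assert ivw(h).se == pytest.approx(
            ivw(h, variance_mode="fixed").se
        )

    def test_random_effects_inflates_under_heterogeneity(self):
        h = make_hset([0.1, 0.2, 0.3], [0.08, 0.01, 0.05])
        assert ivw(h).se > ivw(h, variance_mode="fixed").se

    def test_reorder_and_signflip_invariance(self):
        rng = np.random.default_rng(3)
        g = rng.normal(0.1, 0.05, 10)
        G = 0.15 * g + rng.normal(0, 0.01, 10)
        se_G = rng.uniform(0.005, 0.02, 10)
        base = ivw(make_hset(g, G, se_big_gamma=se_G), "fixed").beta
        perm = rng.permutation(10)
        assert ivw(
            make_hset(g[perm], G[perm], se_big_gamma=se_G[perm]), "fixed"
        ).beta == pytest.approx(base, rel=1e-12)
        assert ivw(
            make_hset(-g, -G, se_big_gamma=se_G), "fixed"
        ).beta == pytest.approx(base, rel=1e-12)

    def test_parameter_recovery(self):
        """DERIVED: mean IVW over 200 replicates within 2 MC SEs of the
        true effect 0.15 (no pleiotropy, N = 50,000, 20 instruments)."""
        ests = []
        for s in range(200):
            st_ = simulate_study(
                SimulationConfig(
                    n_snps=20,
                    n_instruments=20,
                    beta1_true=0.0,
                    beta2_true=0.0,
                    direct_true=0.15,
                    seed=5000 + s,
                )
            )
            hset = harmonize(st_.exposure, st_.outcome)
            ests.append(ivw(hset).beta)
        ests = np.asarray(ests)
        mc_se = ests.std(ddof=1) / np.sqrt(len(ests))
        assert abs(ests.mean() - 0.15) < 2 * mc_se

    def test_empty_set_fatal(self):
        h = make_hset([0.1], [0.02])
        h.table = h.table.iloc[:0]
        with pytest.raises(EstimatorError):
            ivw(h)


class TestEgger:
    def test_exact_line(self):
        g = np.array([0.05, 0.1, 0.15, 0.2])
        G = 0.01 + 0.5 * g
        h = make_hset(g, G)
        slope, (a, se_a, p_a) = egger(h)
        assert slope.beta == pytest.approx(0.5, rel=1e-9)
        assert a == pytest.approx(0.01, rel=1e-9)

    def test_requires_three(self):
        with pytest.raises(EstimatorError, match="Egger"):
            egger(make_hset([0.1, 0.2], [0.02, 0.03]))

    def test_orientation_invariance(self):
        # flipping the sign of (gamma, Gamma) for some SNPs is a no-op
        rng = np.random.default_rng(8)
        g = rng.normal(0.1, 0.04, 12)
        G = 0.005 + 0.3 * g + rng.normal(0, 0.005, 12)
        se_G = rng.uniform(0.005, 0.02, 12)
        base, (a0, _, _) = egger(make_hset(g, G, se_big_gamma=se_G))
        flip = np.where(rng.random(12) < 0.5, -1.0, 1.0)
        alt, (a1, _, _) = egger(
            make_hset(g * flip, G * flip, se_big_gamma=se_G)
        )
        assert alt.beta == pytest.approx(base.beta, rel=1e-12)
        assert a1 == pytest.approx(a0, rel=1e-12)

    def test_intercept_constrained_equals_ivw(self):
        """Oracle equivalence: a through-origin weighted fit (IVW)
        agrees with Egger when the generating intercept is zero and we
        drop the intercept column from the design."""
        rng = np.random.default_rng(5)
        for _ in range(20):
            g = np.abs(rng.normal(0.1, 0.05, 10)) + 0.01
            G = 0.2 * g + rng.normal(0, 0.01, 10)
            se_G = rng.uniform(0.005, 0.02, 10)
            w = 1 / se_G**2
            beta_constrained = np.sum(w * g * G) / np.sum(w * g**2)
            est = ivw(make_hset(g, G, se_big_gamma=se_G), "fixed")
            assert est.beta == pytest.approx(beta_constrained, rel=1e-12)

    def test_balanced_pleiotropy_type_one_error(self):
        """DERIVED: intercept test rejects at ~5% under balanced
        pleiotropy (null for the intercept)."""
        rejections = 0
        n_rep = 400
        for s in range(n_rep):
            st_ = simulate_study(
                SimulationConfig(
                    n_snps=20,
                    n_instruments=20,
                    direct_true=0.1,
                    pleiotropy_mode="balanced",
                    pleiotropy_sd=0.02,
                    seed=40_000 + s,
                )
            )
            hset = harmonize(st_.exposure, st_.outcome)
            _, (_, _, p_a) = egger(hset)
            rejections += p_a < 0.05
        assert 0.02 <= rejections / n_rep <= 0.08

    def test_directional_pleiotropy_less_biased_than_ivw(self):
        """DERIVED: with directional pleiotropy the Egger slope is less
        biased than IVW on average."""
        ivw_err, egger_err = [], []
        for s in range(150):
            st_ = simulate_study(
                SimulationConfig(
                    n_snps=20,
                    n_instruments=20,
                    direct_true=0.1,
                    pleiotropy_mode="directional",
                    pleiotropy_sd=0.03,
                    seed=60_000 + s,
                )
            )
            hset = harmonize(st_.exposure, st_.outcome)
            ivw_err.append(ivw(hset).beta - 0.1)
            egger_err.append(egger(hset)[0].beta - 0.1)
        assert abs(np.mean(egger_err)) < abs(np.mean(ivw_err))


class TestWeightedMedian:
    def test_equal_weights_exact_median(self):
        # equal weights and ratios {0.1, 0.2, 0.3}: p_2 = 0.5 exactly
        h = make_hset([0.1, 0.1, 0.1], [0.01, 0.02, 0.03])
        est = weighted_median(h, n_boot=50, seed=0)
        assert est.beta == pytest.approx(0.2)

    def test_hand_interpolation(self):
        """DERIVED: weights {1,1,2}, ratios {0.1,0.2,0.3} ->
        interpolate between p=0.375 and p=0.75 -> 0.23333."""
        # weights gamma^2/se^2: choose gamma {1,1,sqrt(2)}, se_G = 1
        g = np.array([1.0, 1.0, np.sqrt(2.0)])
        G = np.array([0.1, 0.2, 0.3]) * g
        h = make_hset(g, G, se_big_gamma=1.0)
        est = weighted_median(h, n_boot=50, seed=0)
        assert est.beta == pytest.approx(0.2 + 0.1 * (0.125 / 0.375))

    def test_equals_sample_median_odd_k(self):
        rng = np.random.default_rng(11)
        ratios = rng.normal(0.2, 0.1, 7)
        h = make_hset(np.ones(7), ratios)
        est = weighted_median(h, n_boot=50, seed=0)
        assert est.beta == pytest.approx(np.median(ratios))

    def test_seeded_reproducibility(self):
        h = make_hset([0.1, 0.12, 0.2, 0.15], [0.02, 0.02, 0.05, 0.04])
        a = weighted_median(h, n_boot=200, seed=42)
        b = weighted_median(h, n_boot=200, seed=42)
        assert a.se == b.se
        assert weighted_median(h, n_boot=200, seed=43).se != a.se

    def test_requires_three(self):
        with pytest.raises(EstimatorError):
            weighted_median(make_hset([0.1, 0.2], [0.02, 0.03]))

    def test_robust_to_invalid_instruments(self):
        """DERIVED: 30% directionally pleiotropic instruments bias the
        weighted median less than IVW."""
        ivw_est, med_est = [], []
        for s in range(100):
            st_ = simulate_study(
                SimulationConfig(
                    n_snps=20,
                    n_instruments=20,
                    direct_true=0.1,
                    pleiotropy_mode="directional",
                    pleiotropy_sd=0.05,
                    pleiotropy_frac=0.3,
                    seed=70_000 + s,
                )
            )
            hset = harmonize(st_.exposure, st_.outcome)
            ivw_est.append(ivw(hset).beta)
            med_est.append(weighted_median(hset, n_boot=50, seed=s).beta)
        assert abs(np.mean(med_est) - 0.1) < abs(np.mean(ivw_est) - 0.1)


class TestModeEstimate:
    def test_degenerate_density(self):
        h = make_hset([0.1, 0.2, 0.4], [0.1 * 0.3, 0.2 * 0.3, 0.4 * 0.3])
        est = mode_estimate(h, n_boot=50, seed=0)
        assert est.beta == pytest.approx(0.3)

    def test_mode_ignores_outlier(self):
        """DERIVED: grid-search oracle over the explicit kernel density."""
        ratios = np.array([0.1, 0.1, 0.1, 0.9])
        h = make_hset(np.ones(4), ratios)
        est = mode_estimate(h, n_boot=50, seed=0)
        assert abs(est.beta - 0.1) < 0.05
        # oracle: recompute the kernel density by brute force
        from mrmediate.mr import MODE_GRID_POINTS

        s = np.std(ratios, ddof=1)
        iqr = np.subtract(*np.percentile(ratios, [75, 25]))
        scale = min(s, iqr / 1.349) if iqr > 0 else s
        hbw = 0.9 * scale * 4 ** (-1 / 5)
        grid = np.linspace(
            ratios.min() - 3 * hbw, ratios.max() + 3 * hbw, MODE_GRID_POINTS
        )
        dens = sum(
            np.exp(-0.5 * ((grid - r) / hbw) ** 2) for r in ratios
        )
        assert est.beta == pytest.approx(grid[np.argmax(dens)])

    def test_weighted_mode_follows_dominant_weight(self):
        g = np.array([0.01, 0.01, 1.0, 0.01])
        ratios = np.array([0.5, 0.55, 0.1, 0.6])
        h = make_hset(g, ratios * g)
        est = mode_estimate(h, weighted=True, n_boot=50, seed=0)
        assert abs(est.beta - 0.1) < 0.05

    def test_simple_vs_weighted_label(self):
        h = make_hset([0.1, 0.2, 0.3], [0.02, 0.05, 0.08])
        assert mode_estimate(h, n_boot=20, seed=0).method == "simple_mode"
        assert (
            mode_estimate(h, weighted=True, n_boot=20, seed=0).method
            == "weighted_mode"
        )

    def test_seeded_reproducibility(self):
        h = make_hset([0.1, 0.12, 0.2, 0.15], [0.02, 0.02, 0.05, 0.04])
        a = mode_estimate(h, n_boot=100, seed=9)
        b = mode_estimate(h, n_boot=100, seed=9)
        assert a.se == b.se


class TestCochranQ:
    def test_homogeneous_zero(self):
        h = make_hset([0.1, 0.2, 0.4], [0.02, 0.04, 0.08])
        q, df, p = cochran_q(h)
        assert q == pytest.approx(0.0, abs=1e-20)
        assert df == 2
        assert p == pytest.approx(1.0)

    def test_two_snp_arithmetic(self):
        # ratios 0 and 1, both weights 1, reference 0.5 -> Q = 0.5
        h = make_hset([1.0, 1.0], [0.0, 1.0], se_big_gamma=1.0)
        q, df, p = cochran_q(h, beta_ref=0.5)
        assert q == pytest.approx(0.5)
        assert df == 1

    def test_null_calibration(self):
        """DERIVED: Q p-values approximately uniform with no pleiotropy."""
        pvals = []
        for s in range(300):
            st_ = simulate_study(
                SimulationConfig(
                    n_snps=15,
                    n_instruments=15,
                    gamma_sd=0.1,
                    direct_true=0.1,
                    n_exposure=500_000,
                    n_outcome=500_000,
                    seed=80_000 + s,
                )
            )
            hset = harmonize(st_.exposure, st_.outcome)
            pvals.append(cochran_q(hset)[2])
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01


class TestLeaveOneOut:
    def test_identical_snps_all_rows_equal(self):
        h = make_hset([0.1] * 5, [0.02] * 5)
        loo = leave_one_out(h)
        full = ivw(h).beta
        assert len(loo) == 5
        np.testing.assert_allclose(loo["beta"], full)

    def test_outlier_row_moves_most(self):
        g = np.array([0.1, 0.11, 0.12, 0.1, 0.1])
        ratios = np.array([0.2, 0.21, 0.2, 0.19, 2.0])
        h = make_hset(g, ratios * g)
        loo = leave_one_out(h)
        full = ivw(h).beta
        deltas = (loo["beta"] - full).abs()
        assert loo.loc[deltas.idxmax(), "snp_id"] == "snp4"

    def test_row_count_contract(self, forward_study):
        hset = harmonize(
            forward_study.exposure.iloc[:8], forward_study.outcome
        )
        assert len(leave_one_out(hset)) == len(hset)


class TestOddsRatio:
    def test_paper_total_effect_tag_52_5(self):
        or_, _, _ = to_odds_ratio(0.1515, 0.0)
        assert round(or_, 4) == 1.1636

    def test_paper_total_effect_tag_50_4(self):
        or_, _, _ = to_odds_ratio(0.1464, 0.0)
        assert round(or_, 4) == 1.1577

    def test_zero_beta_symmetric(self):
        or_, lo, hi = to_odds_ratio(0.0, 0.1)
        assert or_ == 1.0
        assert lo * hi == pytest.approx(1.0)

    def test_negative_se_rejected(self):
        with pytest.raises(ValueError):
            to_odds_ratio(0.1, -0.01)


class TestEstimateContracts:
    def test_ci_brackets_beta_and_or_scale(self, forward_study):
        hset = harmonize(forward_study.exposure.iloc[:20], forward_study.outcome)
        for est in all_estimates(hset, n_boot=100, seed=1):
            assert est.ci_low <= est.beta <= est.ci_high
            or_, lo, hi = est.or_scale
            assert or_ == pytest.approx(np.exp(est.beta))
            assert lo == pytest.approx(np.exp(est.ci_low))
            assert hi == pytest.approx(np.exp(est.ci_high))

    def test_sensitivity_report_shapes(self, forward_study):
        hset = harmonize(forward_study.exposure.iloc[:10], forward_study.outcome)
        rep = sensitivity_report(hset)
        k = len(hset)
        assert rep.q_df == k - 1
        assert len(rep.leave_one_out) == k
        assert len(rep.wald_ratios) == k

    def test_wald_ratio_table(self):
        h = make_hset([0.1, -0.2], [0.02, 0.03], se_big_gamma=0.01)
        t = per_snp_wald_ratios(h)
        np.testing.assert_allclose(t["beta"], [0.2, -0.15])
        np.testing.assert_allclose(t["se"], [0.1, 0.05])
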