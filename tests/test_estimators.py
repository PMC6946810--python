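"""Causal-effect estimators: frozen oracles, limiting identities,
equivariance properties, and simulation behaviour."""

import numpy as np
import pytest

import pulmo_mr as pm
from pulmo_mr.containers import HarmonizedSet
from pulmo_mr.estimators import _weighted_median_point


def hset(beta_exp, se_exp, beta_out, se_out):
    return HarmonizedSet.from_arrays(beta_exp, se_exp, beta_out, se_out)


class TestWaldRatio:
    def test_direct_ratio(self):
        res = pm.wald_ratio(0.5, 0.01, 0.2, 0.05)
        assert res.theta == pytest.approx(0.4)
        assert res.se == pytest.approx(0.1)

    def test_zero_outcome_effect(self):
        assert pm.wald_ratio(0.5, 0.01, 0.0, 0.05).theta == 0.0

    def test_negative_exposure_effect(self):
        res = pm.wald_ratio(-0.5, 0.01, 0.2, 0.05)
        assert res.theta == pytest.approx(-0.4)
        assert res.se == pytest.approx(0.1)

    def test_zero_exposure_effect_rejected(self):
        with pytest.raises(ZeroDivisionError):
            pm.wald_ratio(0.0, 0.01, 0.2, 0.05)


class TestIvw:
    def test_two_instrument_hand_oracle(self, two_row_set):
        """theta = 0.4, SE_FE = sqrt(1/200), Q1 = 2, SE_RE = 0.1 — worked
        by hand from the IVW formulas."""
        fe = pm.ivw(two_row_set, random_effects=False)
        re = pm.ivw(two_row_set, random_effects=True)
        assert fe.theta == pytest.approx(0.4, abs=1e-10)
        assert fe.se == pytest.approx(np.sqrt(0.005), abs=1e-10)
        assert re.se == pytest.approx(0.1, abs=1e-10)
        assert re.heterogeneity_scale == pytest.approx(np.sqrt(2.0), abs=1e-10)

    def test_single_instrument_falls_back_to_wald(self):
        res = pm.ivw(hset([0.5], [0.01], [0.2], [0.05]))
        assert res.method == "wald"
        assert res.theta == pytest.approx(0.4)

    def test_homogeneous_ratios_no_inflation(self):
        hs = hset([1.0, 2.0, 0.5], [1e-12] * 3, [0.3, 0.6, 0.15], [0.1, 0.2, 0.05])
        fe = pm.ivw(hs, random_effects=False)
        re = pm.ivw(hs, random_effects=True)
        assert re.se == pytest.approx(fe.se, rel=1e-9)

    def test_re_se_never_below_fe_se(self):
        rng = np.random.default_rng(1)
        for seed in range(20):
            hs = pm.simulate_summary_mr(30, 0.2, seed=seed)
            assert pm.ivw(hs, True).se >= pm.ivw(hs, False).se - 1e-15


class TestMaximumLikelihood:
    def test_nome_limit_equals_fixed_effect_ivw(self):
        hs = pm.simulate_summary_mr(50, 0.3, se_exp=1e-8, seed=1)
        ml = pm.maximum_likelihood(hs)
        fe = pm.ivw(hs, random_effects=False)
        assert ml.theta == pytest.approx(fe.theta, abs=1e-6)

    def test_noiseless_recovers_theta_exactly(self):
        hs = pm.simulate_summary_mr(20, 0.42, se_exp=0.0, se_out=0.0, seed=2)
        # tiny SEs so the likelihood is defined
        hs.table["se_exp"] = 1e-8
        hs.table["se_out"] = 1e-8
        assert pm.maximum_likelihood(hs).theta == pytest.approx(0.42, abs=1e-6)

    def test_recovery_and_bias_vs_ivw(self):
        """With exposure-side noise, profile ML is no more biased than
        ratio-based IVW (which suffers weak-instrument attenuation)."""
        ml_err, ivw_err = [], []
        for seed in range(200):
            hs = pm.simulate_summary_mr(
                50, 0.3, beta_exp_mean=0.06, beta_exp_sd=0.02, se_exp=0.02,
                seed=seed,
            )
            ml_err.append(pm.maximum_likelihood(hs).theta - 0.3)
            ivw_err.append(pm.ivw(hs).theta - 0.3)
        assert abs(np.mean(ml_err)) <= abs(np.mean(ivw_err)) + 0.01
        hs = pm.simulate_summary_mr(150, 0.3, seed=999)
        res = pm.maximum_likelihood(hs)
        assert abs(res.theta - 0.3) < 3 * res.se


class TestWeightedMedian:
    def test_odd_count_equal_weights_is_plain_median(self):
        assert _weighted_median_point(np.array([0.2, 0.4, 0.6]),
                                      np.ones(3)) == pytest.approx(0.4)

    def test_even_count_interpolates(self):
        assert _weighted_median_point(np.array([0.2, 0.4]),
                                      np.ones(2)) == pytest.approx(0.3)

    def test_degenerate_weight_mass(self):
        r = _weighted_median_point(np.array([0.2, 0.4, 0.9]),
                                   np.array([1e-9, 1e-9, 1.0]))
        assert r == pytest.approx(0.9, abs=1e-6)

    def test_bootstrap_se_reasonable_and_seeded(self):
        hs = pm.simulate_summary_mr(50, 0.3, seed=3)
        a = pm.weighted_median(hs, n_bootstrap=200, seed=7)
        b = pm.weighted_median(hs, n_bootstrap=200, seed=7)
        assert a.theta == b.theta and a.se == b.se
        assert 0 < a.se < 0.2

    def test_too_few_instruments_rejected(self):
        with pytest.raises(ValueError):
            pm.weighted_median(hset([1, 1], [0.01] * 2, [0.3, 0.4], [0.1] * 2))


class TestMrEgger:
    def test_exact_line_recovered(self):
        bx = np.array([0.5, 1.0, 1.5, 2.0])
        by = 0.1 + 0.3 * bx
        res = pm.mr_egger(hset(bx, [0.01] * 4, by, [0.1] * 4))
        assert res.egger_intercept == pytest.approx(0.1, abs=1e-10)
        assert res.theta == pytest.approx(0.3, abs=1e-10)
        assert res.heterogeneity_scale == pytest.approx(1.0)  # Q_E = 0

    def test_through_origin_equals_fixed_effect_ivw(self):
        hs = pm.simulate_summary_mr(30, 0.3, seed=4)
        e0 = pm.mr_egger(hs, force_zero_intercept=True)
        fe = pm.ivw(hs, random_effects=False)
        assert e0.theta == pytest.approx(fe.theta, abs=1e-10)

    def test_directional_pleiotropy_detected(self):
        rej = 0
        for seed in range(100):
            hs = pm.simulate_summary_mr(
                150, 0.3, fraction_invalid=1.0, alpha_mean=0.05, alpha_sd=0.02,
                balanced=False, seed=seed,
            )
            rej += pm.mr_egger(hs).egger_intercept_p < 0.05
        assert rej / 100 > 0.5

    def test_constant_exposure_effects_rejected(self):
        with pytest.raises(ValueError):
            pm.mr_egger(hset([1.0] * 4, [0.01] * 4, [0.1, 0.2, 0.3, 0.4], [0.1] * 4))

    def test_ci_at_least_as_wide_as_ivw(self):
        for seed in range(20):
            hs = pm.simulate_summary_mr(40, 0.2, seed=seed)
            assert pm.mr_egger(hs).se >= pm.ivw(hs, False).se - 1e-12


class TestMrRaps:
    def test_squared_loss_no_overdispersion_matches_ivw(self):
        hs = pm.simulate_summary_mr(50, 0.3, se_exp=1e-9, seed=5)
        raps = pm.mr_raps(hs, loss="squared", overdispersion=False)
        fe = pm.ivw(hs, random_effects=False)
        assert raps.theta == pytest.approx(fe.theta, abs=1e-4)

    def test_robust_to_gross_outlier(self):
        """One wildly pleiotropic instrument among 50 clean ones: the robust
        profile score beats IVW most of the time."""
        wins = 0
        for seed in range(200):
            hs = pm.simulate_summary_mr(50, 0.3, seed=seed)
            hs.table.loc[0, "beta_out"] += 1.0  # gross outlier
            err_raps = abs(pm.mr_raps(hs).theta - 0.3)
            err_ivw = abs(pm.ivw(hs).theta - 0.3)
            wins += err_raps < err_ivw
        assert wins / 200 >= 0.8

    def test_overdispersion_estimated_under_pleiotropy(self):
        hs = pm.simulate_summary_mr(
            150, 0.3, fraction_invalid=1.0, alpha_sd=0.08, balanced=True, seed=6
        )
        res = pm.mr_raps(hs)
        assert res.overdispersion > 0

    def test_invalid_loss_rejected(self):
        hs = pm.simulate_summary_mr(10, 0.1, seed=7)
        with pytest.raises(ValueError):
            pm.mr_raps(hs, loss="cauchy")


class TestMvmr:
    def test_single_exposure_reduces_to_ivw(self):
        hs = pm.simulate_summary_mr(30, 0.3, seed=8)
        bx, _, by, sy = hs.arrays()
        mv = pm.mvmr_ivw(bx[:, None], by, sy)[0]
        assert mv.theta == pytest.approx(pm.ivw(hs, True).theta, abs=1e-10)

    def test_exact_two_exposure_system(self):
        rng = np.random.default_rng(9)
        X = rng.normal(0.1, 0.05, (5, 2))
        by = X @ [0.3, -0.2]
        res = pm.mvmr_ivw(X, by, np.full(5, 0.05), ["fev1", "bmi"])
        assert res[0].theta == pytest.approx(0.3, abs=1e-10)
        assert res[1].theta == pytest.approx(-0.2, abs=1e-10)

    def test_duplicated_exposure_column_rejected(self):
        X = np.random.default_rng(10).normal(0.1, 0.05, (5, 1))
        with pytest.raises(ValueError):
            pm.mvmr_ivw(np.column_stack([X, X]), np.zeros(5), np.full(5, 0.05))


class TestEquivariance:
    @pytest.mark.parametrize("method", ["ivw", "ml", "wm", "egger", "raps"])
    def test_scale_equivariance(self, method):
        """Multiplying all exposure effects by c scales theta by 1/c."""
        hs = pm.simulate_summary_mr(40, 0.3, seed=11)
        c = 2.5
        scaled = HarmonizedSet.from_arrays(
            hs.table["beta_exp"] * c, hs.table["se_exp"] * c,
            hs.table["beta_out"], hs.table["se_out"],
        )
        fns = {
            "ivw": lambda s: pm.ivw(s),
            "ml": pm.maximum_likelihood,
            "wm": lambda s: pm.weighted_median(s, n_bootstrap=50, seed=1),
            "egger": pm.mr_egger,
            "raps": pm.mr_raps,
        }
        t1 = fns[method](hs).theta
        t2 = fns[method](scaled).theta
        assert t2 == pytest.approx(t1 / c, rel=1e-4)

    @pytest.mark.parametrize("method", ["ivw", "ml", "wm", "egger", "raps"])
    def test_sign_equivariance_per_variant(self, method):
        """Re-orienting one variant (both betas jointly) changes nothing."""
        hs = pm.simulate_summary_mr(40, 0.3, seed=12)
        flipped = HarmonizedSet(table=hs.table.copy())
        for col in ("beta_exp", "beta_out"):
            flipped.table.loc[3, col] = -flipped.table.loc[3, col]
        fns = {
            "ivw": lambda s: pm.ivw(s),
            "ml": pm.maximum_likelihood,
            "wm": lambda s: pm.weighted_median(s, n_bootstrap=50, seed=1),
            "egger": pm.mr_egger,
            "raps": pm.mr_raps,
        }
        assert fns[method](flipped).theta == pytest.approx(
            fns[method](hs).theta, rel=1e-6
        )

    def test_all_estimators_agree_with_valid_instruments(self):
        hs = pm.simulate_summary_mr(150, 0.3, seed=13)
        results = pm.all_estimators(hs, seed=1, n_bootstrap=200)
        for a in results:
            for b in results:
                joint = np.hypot(a.se, b.se)
                assert abs(a.theta - b.theta) < 2 * joint
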