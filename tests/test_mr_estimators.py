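"""MR estimators against closed forms, independent oracles and invariants."""

import numpy as np
import pytest
import statsmodels.api as sm_api
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from smokemr import (
    InsufficientInstrumentsError,
    MRConfig,
    cochran_q,
    egger,
    i2_gx,
    ivw,
    mean_f,
    mr_raps,
    run_mr,
    simex_egger,
    steiger_filter,
    wald_ratio,
    weighted_median,
    weighted_mode,
)
from smokemr.mr_estimators import (
    _orient,
    weighted_median_point,
    weighted_mode_point,
)
from tests.conftest import clean_sim


def random_instance(rng, J=12):
    g = rng.normal(0.1, 0.05, J)
    g[g == 0] = 0.01
    sg = rng.uniform(0.005, 0.03, J)
    G = rng.normal(0.05, 0.05, J)
    sG = rng.uniform(0.005, 0.05, J)
    return g, sg, G, sG


class TestWaldRatio:
    def test_arithmetic(self):
        est = wald_ratio(0.1, 0.01, 0.05, 0.05)
        assert est.beta == pytest.approx(0.5)
        assert est.se == pytest.approx(0.5)

    def test_zero_outcome_effect(self):
        assert wald_ratio(0.2, 0.01, 0.0, 0.05).beta == 0.0

    def test_zero_exposure_effect_raises(self):
        with pytest.raises(ZeroDivisionError):
            wald_ratio(0.0, 0.01, 0.05, 0.05)

    def test_second_order_se_adds_exposure_inflation_term(self):
        first = wald_ratio(0.1, 0.05, 0.05, 0.05)
        second = wald_ratio(0.1, 0.05, 0.05, 0.05, second_order=True)
        expected = np.sqrt(0.05**2 / 0.1**2 + 0.05**2 * 0.05**2 / 0.1**4)
        assert second.se == pytest.approx(expected)
        assert second.se > first.se


class TestIVW:
    def test_exact_closed_form(self):
        g = np.array([0.1, 0.2])
        G = np.array([0.05, 0.10])
        sG = np.array([0.01, 0.01])
        est = ivw((g, None, G, sG))
        assert est.beta == pytest.approx(0.5, abs=1e-14)
        q, df, p = cochran_q((g, None, G, sG), est.beta)
        assert q == pytest.approx(0.0, abs=1e-20)

    def test_equal_ratios_give_that_ratio_and_zero_q(self):
        g = np.array([0.05, 0.1, 0.3])
        c = 0.7
        est = ivw((g, None, c * g, np.array([0.01, 0.02, 0.03])))
        assert est.beta == pytest.approx(c, abs=1e-12)

    def test_single_snp_delegates_to_wald(self):
        est = ivw((np.array([0.1]), np.array([0.01]), np.array([0.05]), np.array([0.05])))
        assert est.method == "Wald"
        assert est.beta == pytest.approx(0.5)

    def test_matches_generic_wls_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            g, sg, G, sG = random_instance(rng)
            est = ivw((g, sg, G, sG))
            wls = sm_api.WLS(G, g[:, None], weights=1 / sG**2).fit()
            assert est.beta == pytest.approx(wls.params[0], abs=1e-10)


class TestEgger:
    def test_exact_linear_data(self):
        g = np.linspace(0.05, 0.3, 6)
        G = 0.02 + 0.5 * g
        sG = np.full(6, 0.01)
        res = egger((g, None, G, sG))
        assert res.estimate.beta == pytest.approx(0.5, abs=1e-12)
        assert res.intercept == pytest.approx(0.02, abs=1e-12)

    def test_matches_generic_wls_with_intercept(self):
        rng = np.random.default_rng(43)
        for _ in range(50):
            g, sg, G, sG = random_instance(rng)
            go, Go = _orient(g, G)
            res = egger((g, sg, G, sG))
            X = sm_api.add_constant(go)
            wls = sm_api.WLS(Go, X, weights=1 / sG**2).fit()
            assert res.estimate.beta == pytest.approx(wls.params[1], abs=1e-10)
            assert res.intercept == pytest.approx(wls.params[0], abs=1e-10)

    def test_too_few_snps(self):
        with pytest.raises(InsufficientInstrumentsError):
            egger((np.array([0.1, 0.2]), None, np.array([0.1, 0.2]), np.array([0.01, 0.01])))

    def test_intercept_constrained_egger_equals_fixed_effect_ivw(self):
        """Through-origin weighted regression IS fixed-effects IVW."""
        rng = np.random.default_rng(44)
        g, sg, G, sG = random_instance(rng)
        est = ivw((g, sg, G, sG), random_effects=False)
        wls = sm_api.WLS(G, g[:, None], weights=1 / sG**2).fit()
        assert est.beta == pytest.approx(wls.params[0], abs=1e-12)
        assert est.se == pytest.approx(1 / np.sqrt(np.sum(g**2 / sG**2)), abs=1e-12)


class TestHeterogeneityDiagnostics:
    def test_q_zero_for_proportional_data(self):
        g = np.array([0.1, 0.2, 0.3])
        q, df, p = cochran_q((g, None, 0.4 * g, np.array([0.01, 0.01, 0.01])), 0.4)
        assert q == pytest.approx(0.0, abs=1e-20)
        assert df == 2 and p == pytest.approx(1.0)

    def test_q_formula_recomputation(self):
        rng = np.random.default_rng(45)
        g, sg, G, sG = random_instance(rng)
        beta = 0.37
        q, df, p = cochran_q((g, sg, G, sG), beta)
        assert q == pytest.approx(np.sum((G - beta * g) ** 2 / sG**2))
        assert p == pytest.approx(stats.chi2.sf(q, df))

    def test_q_mean_matches_chi_square_under_model(self):
        """Under a correctly specified model Q ~ chi2(J-1)."""
        rng = np.random.default_rng(46)
        J, reps = 10, 1000
        qs = np.empty(reps)
        for r in range(reps):
            g = rng.normal(0.2, 0.05, J)
            sG = rng.uniform(0.01, 0.03, J)
            G = 0.5 * g + sG * rng.standard_normal(J)
            est = ivw((g, None, G, sG))
            qs[r], _, _ = cochran_q((g, None, G, sG), est.beta)
        # estimating beta costs one df: E[Q] is a bit under J-1
        assert abs(qs.mean() - (J - 1)) < 0.5

    def test_i2gx_identical_effects_clamped_to_zero(self):
        assert i2_gx([0.1, 0.1, 0.1], [0.01, 0.02, 0.01]) == 0.0

    def test_i2gx_tends_to_one_with_tiny_errors(self):
        assert i2_gx([0.1, 0.2, 0.3], [1e-6, 1e-6, 1e-6]) > 0.999999

    def test_i2gx_formula_recomputation(self):
        rng = np.random.default_rng(47)
        g, sg, _, _ = random_instance(rng)
        w = 1 / sg**2
        gbar = np.sum(w * g) / np.sum(w)
        q = np.sum(w * (g - gbar) ** 2)
        assert i2_gx(g, sg) == pytest.approx(max(0, (q - (len(g) - 1)) / q))

    def test_mean_f(self):
        assert mean_f([0.1], [0.01]) == pytest.approx(100.0)
        assert mean_f([0.1, 0.1 * np.sqrt(3)], [0.01, 0.01]) == pytest.approx(200.0)
        rng = np.random.default_rng(48)
        g, sg, _, _ = random_instance(rng)
        assert mean_f(g, sg) == pytest.approx(np.mean(g**2 / sg**2))


class TestWeightedMedian:
    def test_equal_weights_odd_count(self):
        assert weighted_median_point(np.array([1.0, 2.0, 3.0]), np.ones(3)) == pytest.approx(2.0)

    def test_dominant_weight_pulls_to_that_ratio(self):
        ratios = np.array([1.0, 2.0, 5.0])
        weights = np.array([1.0, 1e7, 1.0])
        assert weighted_median_point(ratios, weights) == pytest.approx(2.0, abs=1e-4)

    def test_matches_cumulative_interpolation_oracle(self):
        rng = np.random.default_rng(49)
        for _ in range(50):
            J = rng.integers(3, 30)
            ratios = rng.normal(0.5, 1.0, J)
            weights = rng.uniform(0.1, 5.0, J)
            order = np.argsort(ratios)
            r, w = ratios[order], weights[order]
            cum = (np.cumsum(w) - 0.5 * w) / w.sum()
            expected = float(np.interp(0.5, cum, r))
            assert weighted_median_point(ratios, weights) == pytest.approx(expected, abs=1e-12)

    def test_full_estimator_returns_bootstrap_se(self, small_dataset):
        est = weighted_median(small_dataset, n_boot=200, seed=1)
        assert est.se > 0 and est.ci_low < est.beta < est.ci_high


class TestWeightedMode:
    def test_plurality_of_identical_ratios(self):
        g = np.array([0.1, 0.2, 0.4, 0.25, 0.3])
        G = 0.8 * g
        G[3] = 2.0 * g[3]  # one outlier
        sG = np.full(5, 0.01)
        est = weighted_mode((g, None, G, sG), n_boot=50, seed=2)
        assert est.beta == pytest.approx(0.8, abs=0.05)

    def test_outlier_insensitivity(self):
        rng = np.random.default_rng(50)
        g = rng.uniform(0.1, 0.3, 20)
        sG = np.full(20, 0.01)
        G = 0.5 * g + 0.002 * rng.standard_normal(20)
        G[0] = 5.0 * g[0]
        est = weighted_mode((g, None, G, sG), n_boot=50, seed=3)
        assert abs(est.beta - 0.5) < 0.1

    def test_vanishing_bandwidth_returns_max_weight_ratio(self):
        ratios = np.array([1.0, 2.0, 3.0])
        weights = np.array([1.0, 5.0, 2.0])
        assert weighted_mode_point(ratios, weights, 1e-12) == pytest.approx(2.0)


class TestRAPS:
    def test_no_exposure_noise_simple_equals_fixed_effect_ivw(self, small_dataset):
        g, sg, G, sG = small_dataset
        zero = np.zeros_like(g)
        est = mr_raps((g, zero, G, sG))
        fe = ivw((g, zero, G, sG), random_effects=False)
        assert est.beta == pytest.approx(fe.beta, abs=1e-8)

    def test_all_null_outcome_effects_give_zero(self):
        g = np.array([0.1, 0.2, 0.3, 0.15])
        est = mr_raps((g, np.full(4, 0.01), np.zeros(4), np.full(4, 0.01)))
        assert est.beta == pytest.approx(0.0, abs=1e-8)

    def test_huber_and_overdispersion_paths_run(self, small_dataset):
        simple = mr_raps(small_dataset)
        robust = mr_raps(small_dataset, loss="huber")
        over = mr_raps(small_dataset, overdispersion=True)
        for est in (simple, robust, over):
            assert np.isfinite(est.beta) and est.se > 0
        assert robust.beta == pytest.approx(simple.beta, abs=0.1)

    def test_recovers_truth_in_large_sample(self):
        biases = []
        for seed in range(30):
            (g, sg, G, sG), _ = clean_sim(seed=900 + seed, n_snp=100)
            biases.append(mr_raps((g, sg, G, sG)).beta - np.log(2))
        assert abs(np.mean(biases)) < 3 * np.std(biases) / np.sqrt(30) + 1e-3


class TestSIMEX:
    def test_no_measurement_error_equals_plain_unweighted_egger(self, small_dataset):
        g, sg, G, sG = small_dataset
        zero = np.zeros_like(g)
        est = simex_egger((g, zero, G, sG), n_boot=50, seed=4, se_boot=10)
        go, Go = _orient(g, G)
        ols = sm_api.OLS(Go, sm_api.add_constant(go)).fit()
        assert est.beta == pytest.approx(ols.params[1], abs=1e-10)

    def test_lambda_zero_grid_reproduces_naive_slope(self, small_dataset):
        g, sg, G, sG = small_dataset
        est = simex_egger((g, sg, G, sG), lambda_grid=(0.0,), n_boot=50, seed=5, se_boot=10)
        go, Go = _orient(g, G)
        ols = sm_api.OLS(Go, sm_api.add_constant(go)).fit()
        assert est.beta == pytest.approx(ols.params[1], abs=1e-10)

    def test_corrects_attenuation_in_dilution_scenario(self):
        """SIMEX moves the diluted Egger slope back toward the truth."""
        theta = np.log(2)
        wins = 0
        reps = 40
        for r in range(reps):
            (g, sg, G, sG), _ = clean_sim(
                seed=7000 + r, n_snp=50, gamma_sd=0.02,
                n_exposure=10_000, n_outcome=500_000,
            )
            go, Go = _orient(g, G)
            naive = sm_api.OLS(Go, sm_api.add_constant(go)).fit().params[1]
            est = simex_egger((g, sg, G, sG), n_boot=400, seed=100 + r, se_boot=5)
            if abs(est.beta - theta) < abs(naive - theta):
                wins += 1
        assert wins / reps >= 0.7


class TestSteiger:
    def test_strong_exposure_weak_outcome_is_correct_direction(self):
        g = np.array([0.3, 0.25, 0.2])
        G = np.array([0.001, 0.002, 0.001])
        res = steiger_filter((g, None, G, None), 100_000, 100_000, eaf=np.array([0.3, 0.4, 0.2]))
        assert all(f == "correct" for f in res.flags)
        assert res.overall_correct and res.pval < 0.05

    def test_exact_tie_is_indeterminate_and_retained(self):
        g = np.array([0.2, 0.2, 0.2])
        res = steiger_filter((g, None, g.copy(), None), 1e5, 1e5, eaf=np.array([0.3, 0.3, 0.3]))
        assert all(f == "indeterminate" for f in res.flags)
        assert len(res.retained_index) == 3

    def test_missing_eaf_excluded_from_filtering(self):
        g = np.array([0.3, 0.3])
        G = np.array([0.01, 0.01])
        res = steiger_filter((g, None, G, None), 1e5, 1e5, eaf=np.array([0.3, np.nan]))
        assert list(res.flags) == ["correct", "unknown"]
        assert len(res.retained_index) == 2

    def test_correct_fraction_grows_with_sample_size(self):
        fracs = []
        for n in (5_000, 500_000):
            (g, sg, G, sG), truth = clean_sim(seed=77, n_snp=100, n_exposure=n, n_outcome=n)
            res = steiger_filter((g, sg, G, sG), n, n, eaf=truth["eaf"].to_numpy())
            fracs.append(np.mean(res.flags == "correct"))
        assert fracs[1] >= fracs[0]
        assert fracs[1] > 0.95


class TestRunMR:
    def test_all_methods_reported_with_diagnostics(self, small_dataset):
        cfg = MRConfig(n_boot=50, seed=6)
        results, diag = run_mr(small_dataset, cfg)
        methods = set(results["method"])
        assert {"IVW", "Egger", "weighted-median", "weighted-mode", "RAPS"} <= methods
        assert np.isfinite(diag.cochran_q) and diag.q_df == len(small_dataset[0]) - 1
        assert 0 <= diag.i2_gx <= 1 and diag.mean_f > 0
        # binary outcome: OR columns present and consistent
        ivw_row = results[results["method"] == "IVW"].iloc[0]
        assert ivw_row["or"] == pytest.approx(np.exp(ivw_row["beta"]))

    def test_single_snp_yields_wald_row_only(self):
        res, _ = run_mr((np.array([0.1]), np.array([0.01]), np.array([0.05]), np.array([0.05])))
        assert list(res["method"]) == ["Wald"]

    def test_simex_row_added_when_i2gx_low(self):
        (g, sg, G, sG), _ = clean_sim(seed=88, n_snp=30, gamma_sd=0.02,
                                      n_exposure=10_000, n_outcome=500_000)
        assert i2_gx(g, sg) < 0.9
        cfg = MRConfig(n_boot=100, seed=7)
        results, _ = run_mr((g, sg, G, sG), cfg)
        assert "Egger-SIMEX" in set(results["method"])

    def test_directional_pleiotropy_biases_ivw_and_moves_intercept(self):
        (g, sg, G, sG), _ = clean_sim(
            seed=99, n_snp=100, pleiotropy="directional", alpha_mean=0.1,
            alpha_sd=0.02, invalid_frac=1.0, gamma_orientation="positive",
        )
        cfg = MRConfig(n_boot=50, seed=8)
        results, diag = run_mr((g, sg, G, sG), cfg)
        ivw_beta = results.loc[results["method"] == "IVW", "beta"].iloc[0]
        assert ivw_beta - np.log(2) > 0.1  # biased upward
        assert diag.intercept_pval < 0.01

    def test_method_failure_annotated_not_fatal(self):
        # two SNPs: median/mode/Egger/RAPS all need >= 3; IVW still reported
        res, _ = run_mr((np.array([0.1, 0.2]), np.array([0.01, 0.01]),
                         np.array([0.05, 0.1]), np.array([0.01, 0.01])))
        assert "IVW" in set(res["method"])
        failed = res[res["note"].str.startswith("failed")]
        assert len(failed) >= 3


class TestInvariances:
    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(k=st.floats(0.1, 10), seed=st.integers(0, 100))
    def test_outcome_scale_equivariance(self, k, seed):
        """Multiplying all outcome effects and SEs by k scales beta and se by k."""
        rng = np.random.default_rng(seed)
        g, sg, G, sG = random_instance(rng)
        base_ivw = ivw((g, sg, G, sG))
        scaled_ivw = ivw((g, sg, k * G, k * sG))
        assert scaled_ivw.beta == pytest.approx(k * base_ivw.beta, rel=1e-9)
        assert scaled_ivw.se == pytest.approx(k * base_ivw.se, rel=1e-9)

        base_eg = egger((g, sg, G, sG))
        scaled_eg = egger((g, sg, k * G, k * sG))
        assert scaled_eg.estimate.beta == pytest.approx(k * base_eg.estimate.beta, rel=1e-9)

        med0 = weighted_median_point(G / g, g**2 / sG**2)
        med1 = weighted_median_point(k * G / g, g**2 / (k * sG) ** 2)
        assert med1 == pytest.approx(k * med0, rel=1e-9)

        raps0 = mr_raps((g, sg, G, sG))
        raps1 = mr_raps((g, sg, k * G, k * sG))
        assert raps1.beta == pytest.approx(k * raps0.beta, rel=1e-5, abs=1e-7)

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(seed=st.integers(0, 100))
    def test_instrument_orientation_invariance(self, seed):
        """Jointly sign-flipping (gamma_j, Gamma_j) pairs changes nothing."""
        rng = np.random.default_rng(seed)
        g, sg, G, sG = random_instance(rng)
        s = rng.choice([-1.0, 1.0], g.size)
        flipped = (s * g, sg, s * G, sG)
        assert ivw(flipped).beta == pytest.approx(ivw((g, sg, G, sG)).beta, rel=1e-12)
        assert egger(flipped).estimate.beta == pytest.approx(
            egger((g, sg, G, sG)).estimate.beta, rel=1e-12
        )
        m0 = weighted_median_point(G / g, g**2 / sG**2)
        m1 = weighted_median_point((s * G) / (s * g), (s * g) ** 2 / sG**2)
        assert m1 == pytest.approx(m0, rel=1e-12)
        assert mr_raps(flipped).beta == pytest.approx(
            mr_raps((g, sg, G, sG)).beta, rel=1e-6, abs=1e-8
        )
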