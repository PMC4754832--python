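"""Model-layer tests: the logistic fitter against closed forms and
statsmodels, Nagelkerke attribution, interaction tests, gene-environment
correlation, permutation inference and the sensitivity analysis."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.special import expit

from prsgxe.gxe import (
    AnalysisPlan,
    RankDeficiencyError,
    SeparationError,
    bonferroni_threshold,
    delta_r2_excluding_pcs,
    figure_logodds_by_category,
    fit_linear,
    fit_logistic,
    ge_correlation,
    nagelkerke_r2,
    permutation_empirical_p,
    run_threshold_grid,
    sensitivity_exclude_depressed,
)
from prsgxe.gxe import test_additive_interaction as additive_interaction_test
from prsgxe.gxe import test_multiplicative_interaction as multiplicative_interaction_test
from prsgxe.scoring import ScoreMatrix


def _null_data(rng, n=600, k_pc=2):
    prs = rng.standard_normal(n)
    env = rng.poisson(2.0, n).astype(float)
    pcs = rng.standard_normal((n, k_pc)) / np.sqrt(n)
    y = (rng.random(n) < 0.5).astype(float)
    return y, prs, env, pcs


class TestFitLogistic:
    def test_balanced_intercept_only(self):
        y = np.array([0.0, 1.0] * 50)
        fit = fit_logistic(np.ones((100, 1)), y)
        assert fit.beta[0] == pytest.approx(0.0, abs=1e-8)
        assert fit.loglik == pytest.approx(100 * np.log(0.5), rel=1e-12)

    def test_two_by_two_closed_form(self):
        # cells (a,b,c,d) = (30,20,10,40): slope = log(ad/bc) = log(6)
        x = np.concatenate([np.ones(50), np.zeros(50)])
        y = np.concatenate([np.ones(30), np.zeros(20), np.ones(10), np.zeros(40)])
        fit = fit_logistic(np.column_stack([np.ones(100), x]), y)
        assert fit.beta[1] == pytest.approx(np.log(6.0), abs=1e-8)
        assert fit.beta[0] == pytest.approx(np.log(10 / 40), abs=1e-8)

    def test_consistency_on_simulation(self):
        rng = np.random.default_rng(5)
        n = 20000
        x = rng.standard_normal(n)
        y = (rng.random(n) < expit(0.5 * x)).astype(float)
        fit = fit_logistic(np.column_stack([np.ones(n), x]), y)
        assert 0.45 <= fit.beta[1] <= 0.55

    def test_matches_statsmodels(self):
        rng = np.random.default_rng(8)
        n = 500
        X = np.column_stack([np.ones(n), rng.standard_normal((n, 3))])
        y = (rng.random(n) < expit(X @ np.array([0.2, 0.5, -0.3, 0.0]))).astype(float)
        ours = fit_logistic(X, y)
        ref = sm.Logit(y, X).fit(disp=0)
        np.testing.assert_allclose(ours.beta, ref.params, atol=1e-6)
        np.testing.assert_allclose(ours.se, ref.bse, rtol=1e-5)
        assert ours.loglik == pytest.approx(ref.llf, abs=1e-6)

    def test_separation_raises_naming_column(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(200)
        y = (x > 0).astype(float)
        with pytest.raises(SeparationError, match="slope"):
            fit_logistic(np.column_stack([np.ones(200), x]), y,
                         colnames=["intercept", "slope"])

    def test_rank_deficiency_raises_naming_column(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(100)
        y = (rng.random(100) < 0.5).astype(float)
        X = np.column_stack([np.ones(100), x, 2 * x])
        with pytest.raises(RankDeficiencyError, match="dup"):
            fit_logistic(X, y, colnames=["intercept", "x", "dup"])

    def test_constant_outcome_raises(self):
        with pytest.raises(ValueError, match="constant"):
            fit_logistic(np.ones((10, 1)), np.ones(10))


class TestNagelkerke:
    def test_no_improvement_is_zero(self):
        assert nagelkerke_r2(-60.0, -60.0, 100) == 0.0

    def test_perfect_prediction_is_one(self):
        assert nagelkerke_r2(0.0, -60.0, 100) == pytest.approx(1.0)

    def test_plugin_oracle(self):
        # independent arithmetic: n=100, ll0 = 100 log .5, llf = ll0 + 5
        ll0 = 100 * np.log(0.5)
        expected = (1 - np.exp(2 * (-5.0) / 100)) / (1 - np.exp(2 * ll0 / 100))
        assert nagelkerke_r2(ll0 + 5, ll0, 100) == pytest.approx(expected, rel=1e-12)

    def test_degenerate_null_errors(self):
        with pytest.raises(ValueError):
            nagelkerke_r2(0.0, 0.0, 10)

    def test_invalid_ordering_errors(self):
        with pytest.raises(ValueError):
            nagelkerke_r2(-50.0, -40.0, 100)


class TestDeltaR2:
    def test_duplicated_covariate_errors(self):
        rng = np.random.default_rng(1)
        y, prs, env, pcs = _null_data(rng)
        with pytest.raises(RankDeficiencyError):
            delta_r2_excluding_pcs(y, prs[:, None], pcs, other_covariates=prs[:, None])

    def test_loglik_decomposition_identity(self):
        # likelihood-ratio chain: (ll_full - ll_reduced) + (ll_reduced -
        # ll_null) = ll_full - ll_null on the log scale
        rng = np.random.default_rng(2)
        n = 800
        pcs = rng.standard_normal((n, 2)) / np.sqrt(n)
        prs = rng.standard_normal(n)
        y = (rng.random(n) < expit(0.3 * prs + 10 * pcs[:, 0])).astype(float)
        res = delta_r2_excluding_pcs(y, prs[:, None], pcs)
        lhs = (res["loglik_full"] - res["loglik_reduced"]) + (
            res["loglik_reduced"] - res["loglik_null"]
        )
        assert lhs == pytest.approx(res["loglik_full"] - res["loglik_null"], abs=1e-10)
        assert 0 <= res["delta_r2"] <= 1
        assert 0 <= res["r2_full"] <= 1

    def test_null_term_small_delta(self):
        rng = np.random.default_rng(3)
        vals = []
        for _ in range(10):
            y, prs, env, pcs = _null_data(rng, n=1000)
            vals.append(delta_r2_excluding_pcs(y, prs[:, None], pcs)["delta_r2"])
        assert np.mean(vals) < 0.005


class TestInteractions:
    def _interaction_world(self, rng, n=1200, or_gxe=1.0):
        prs = rng.standard_normal(n)
        env = (rng.random(n) < 0.4).astype(float)
        pcs = rng.standard_normal((n, 2)) / np.sqrt(n)
        eta = -0.3 + 0.2 * prs + 0.5 * env + np.log(or_gxe) * prs * env
        y = (rng.random(n) < expit(eta)).astype(float)
        return y, prs, env, pcs

    def test_multiplicative_recovers_interaction(self):
        rng = np.random.default_rng(11)
        ests, ses = [], []
        for _ in range(30):
            y, prs, env, pcs = self._interaction_world(rng, n=2000, or_gxe=1.5)
            r = multiplicative_interaction_test(y, prs, env, pcs)
            ests.append(r.estimate)
            ses.append(r.se)
        mean = np.mean(ests)
        sem = np.std(ests, ddof=1) / np.sqrt(len(ests))
        assert abs(mean - np.log(1.5)) < 2 * sem + 0.01
        # CI construction on the estimation scale
        r = multiplicative_interaction_test(y, prs, env, pcs)
        assert r.ci_low == pytest.approx(np.exp(r.estimate - 1.959964 * r.se))
        assert r.ci_high == pytest.approx(np.exp(r.estimate + 1.959964 * r.se))

    def test_permutation_asymptotic_concordance(self):
        # under a modest effect both p-values estimate the same quantity;
        # they agree within Monte-Carlo error of the permutation draw
        rng = np.random.default_rng(21)
        y, prs, env, pcs = self._interaction_world(rng, n=700, or_gxe=1.25)
        B = 1999
        r = multiplicative_interaction_test(y, prs, env, pcs, B=B,
                                            rng=np.random.default_rng(7))
        mc = 2 * np.sqrt(max(r.p_asymptotic, 0.01) * (1 - r.p_asymptotic) / B)
        assert abs(r.p_empirical - r.p_asymptotic) < mc + 2 / (B + 1)

    def test_additive_null_r2_increment_small(self):
        rng = np.random.default_rng(31)
        vals = []
        for _ in range(10):
            n = 2669
            y = np.concatenate([np.ones(1605), np.zeros(1064)])
            prs = rng.standard_normal(n)
            env = rng.poisson(2.0, n).astype(float)
            pcs = rng.standard_normal((n, 2)) / np.sqrt(n)
            r = additive_interaction_test(y, prs, env, pcs)
            vals.append(r.delta_r2)
        assert np.mean(vals) < 0.002

    def test_pure_multiplicativity_departs_from_additivity(self):
        # strong multiplicative main effects with no product-scale
        # interaction imply additive-scale departure; the additive test
        # rejects well above its nominal level
        rng = np.random.default_rng(41)
        rejections = 0
        reps = 40
        for _ in range(reps):
            n = 3000
            prs = rng.standard_normal(n)
            env = (rng.random(n) < 0.5).astype(float)
            pcs = rng.standard_normal((n, 2)) / np.sqrt(n)
            y = (rng.random(n) < expit(-1.2 + 1.2 * prs + 1.5 * env)).astype(float)
            r = additive_interaction_test(y, prs, env, pcs)
            rejections += r.p_asymptotic < 0.05
        assert rejections / reps > 0.3

    def test_nan_rows_dropped(self):
        rng = np.random.default_rng(51)
        y, prs, env, pcs = self._interaction_world(rng, n=500)
        env = env.copy()
        env[:100] = np.nan
        r = multiplicative_interaction_test(y, prs, env, pcs)
        assert r.n_used == 400


class TestGeCorrelation:
    def test_recovers_injected_correlation(self):
        # environment built as 0.1 * prs + noise within cases only
        rng = np.random.default_rng(61)
        ests, ses = [], []
        for _ in range(200):
            n = 1000
            case = np.zeros(n, dtype=bool)
            case[:600] = True
            prs = rng.standard_normal(n)
            pcs = rng.standard_normal((n, 2)) / np.sqrt(n)
            env = rng.standard_normal(n)
            env[case] += 0.1 * prs[case]
            r = ge_correlation(env, prs, pcs, subset=case)
            ests.append(r.estimate)
        mean = np.mean(ests)
        sem = np.std(ests, ddof=1) / np.sqrt(len(ests))
        assert abs(mean - 0.1) < 2 * sem

    def test_null_in_controls(self):
        rng = np.random.default_rng(62)
        n = 1000
        case = np.zeros(n, dtype=bool)
        case[:600] = True
        prs = rng.standard_normal(n)
        pcs = rng.standard_normal((n, 2)) / np.sqrt(n)
        env = rng.standard_normal(n)
        env[case] += 0.5 * prs[case]
        r = ge_correlation(env, prs, pcs, subset=~case)
        assert r.p_asymptotic > 0.01

    def test_constant_env_errors(self):
        rng = np.random.default_rng(63)
        with pytest.raises(ValueError, match="constant"):
            ge_correlation(np.ones(50), rng.standard_normal(50),
                           rng.standard_normal((50, 2)))

    def test_dependent_only_rge_world(self):
        # generator built with genetic correlation to dependent SLEs only:
        # detected for dependent counts, null for independent counts
        from prsgxe.simulate import SimulationConfig, simulate_environment

        cfg = SimulationConfig(rge=0.3, rge_dependent_only=True, seed=71)
        n = 6000
        rng = np.random.default_rng(71)
        z = rng.standard_normal(n)
        env = simulate_environment(cfg, np.full(n, 45.0), np.zeros(n), rng, z_g=z)
        pcs = rng.standard_normal((n, 2)) / np.sqrt(n)
        r_dep = ge_correlation(env["sle_dependent"].to_numpy(dtype=float), z, pcs)
        r_ind = ge_correlation(env["sle_independent"].to_numpy(dtype=float), z, pcs)
        assert r_dep.p_asymptotic < 1e-6
        assert r_ind.p_asymptotic > 0.01


class TestPermutation:
    def test_null_observation_p_one(self):
        rng = np.random.default_rng(1)
        y = rng.standard_normal(100)
        p = permutation_empirical_p(0.0, lambda yp: float(np.mean(yp)), y, 99, rng)
        assert p == 1.0

    def test_extreme_observation(self):
        rng = np.random.default_rng(2)
        y = rng.standard_normal(100)
        B = 199
        p = permutation_empirical_p(1e9, lambda yp: float(np.mean(yp)), y, B, rng)
        assert p == pytest.approx(1 / (B + 1))

    def test_failures_discarded_then_error(self):
        rng = np.random.default_rng(3)
        y = np.arange(100.0)
        calls = {"n": 0}

        def flaky(yp):
            calls["n"] += 1
            raise SeparationError("always fails")

        with pytest.raises(RuntimeError, match="failed"):
            permutation_empirical_p(1.0, flaky, y, 100, rng)


class TestBonferroni:
    @pytest.mark.parametrize("alpha,m,expected", [(0.05, 10, 0.005), (0.05, 1, 0.05), (0.01, 4, 0.0025)])
    def test_values(self, alpha, m, expected):
        assert bonferroni_threshold(alpha, m) == pytest.approx(expected)

    def test_validation(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.0, 10)
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)


class TestSensitivity:
    def test_no_exclusion_identical(self):
        rng = np.random.default_rng(5)
        case = np.array([True] * 50 + [False] * 50)
        bdi = np.where(case, rng.integers(0, 20, 100), 0.0)

        def analysis(keep):
            return keep.sum()

        assert sensitivity_exclude_depressed(analysis, bdi, case, 63.0) == 100

    def test_empty_case_subset_errors(self):
        case = np.array([True, True, False])
        bdi = np.array([40.0, 45.0, 0.0])
        with pytest.raises(ValueError, match="no cases"):
            sensitivity_exclude_depressed(lambda k: k, bdi, case, 29.0)

    def test_recall_bias_attenuates_after_exclusion(self):
        # reported environment inflated in proportion to PRS among severely
        # depressed cases only: the spurious gene-environment correlation
        # weakens once those cases are excluded
        rng = np.random.default_rng(6)
        n = 2000
        case = np.ones(n, dtype=bool)
        prs = rng.standard_normal(n)
        bdi = rng.uniform(0, 60, n)
        env = rng.standard_normal(n)
        severe = bdi >= 29
        env[severe] += 0.5 * prs[severe]
        pcs = rng.standard_normal((n, 2)) / np.sqrt(n)

        full = ge_correlation(env, prs, pcs, subset=case)

        def analysis(keep):
            return ge_correlation(env[keep], prs[keep], pcs[keep])

        sens = sensitivity_exclude_depressed(analysis, bdi, case, 29.0)
        assert full.p_asymptotic < 1e-6
        assert abs(sens.estimate) < abs(full.estimate) / 2


class TestRunGrid:
    def _score_matrix(self, rng, n, grid):
        base = rng.standard_normal(n)
        raw = np.column_stack([base + 0.3 * rng.standard_normal(n) for _ in grid])
        std = (raw - raw.mean(axis=0)) / raw.std(axis=0, ddof=1)
        return ScoreMatrix(sample_ids=np.arange(n).astype(str), thresholds=tuple(grid),
                           raw=raw, std=std, snp_counts=list(range(1, len(grid) + 1)))

    def test_cardinality_nine_rows(self):
        rng = np.random.default_rng(9)
        n = 400
        grid = (0.0001, 0.001, 0.01, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5)
        sm_ = self._score_matrix(rng, n, grid)
        pcs = rng.standard_normal((n, 2)) / np.sqrt(n)
        y = (rng.random(n) < 0.5).astype(float)
        env = rng.poisson(2.0, n).astype(float)
        plan = AnalysisPlan(models=("multiplicative",), environments=("e",),
                            grid=grid, B=0, seed=1)
        res = run_threshold_grid(plan, sm_, pcs, y, {"e": env})
        assert len(res) == 9
        assert set(res["p_t"]) == set(grid)

    def test_familywise_null_no_stars(self):
        # replicate grids under the complete null: at the 0.005 Bonferroni
        # threshold, >= 95% of grids show no significant interaction
        rng = np.random.default_rng(10)
        grid = (0.0001, 0.001, 0.01, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5)
        clean = 0
        reps = 20
        for rep in range(reps):
            n = 500
            sm_ = self._score_matrix(rng, n, grid)
            pcs = rng.standard_normal((n, 2)) / np.sqrt(n)
            y = (rng.random(n) < 0.5).astype(float)
            env = rng.poisson(2.0, n).astype(float)
            plan = AnalysisPlan(models=("multiplicative",), environments=("e",),
                                grid=grid, B=0, m=10, seed=rep)
            res = run_threshold_grid(plan, sm_, pcs, y, {"e": env})
            clean += not res["significant"].any()
        assert clean / reps >= 0.95

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError):
            AnalysisPlan(models=("bogus",))


class TestFigure3:
    def test_inverse_interaction_slope_pattern(self):
        # none: risk rises with PRS; moderate/severe: highest-risk members
        # have lower-than-average PRS (downward slope)
        rng = np.random.default_rng(12)
        n = 3000
        prs = rng.standard_normal(n)
        cat = rng.choice(["none", "mild", "moderate_severe"], n, p=[0.5, 0.3, 0.2])
        eta = np.where(cat == "none", -0.5 + 0.6 * prs,
                       np.where(cat == "mild", 0.3, 1.0 - 0.6 * prs))
        y = (rng.random(n) < expit(eta)).astype(float)
        fig = figure_logodds_by_category(y, prs, cat)
        slopes = {}
        for c, grp in fig.groupby("category"):
            slopes[c] = np.polyfit(grp["prs"], grp["logodds"], 1)[0]
        assert slopes["none"] > 0.3
        assert slopes["moderate_severe"] < -0.3
        assert abs(slopes["mild"]) < 0.25
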