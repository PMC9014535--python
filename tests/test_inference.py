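import itertools

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from neuroimmune.inference import (
    RepeatedMeasuresPermutationLMM,
    RobustPermutationRegressor,
    bonferroni_threshold,
    effect_size_label,
    fit_lmm_repeated,
    permutation_p_lmm,
    robust_fit,
    robust_permutation_wald,
    standardized_beta,
)

from conftest import make_long_repeated


class TestThresholdsAndLabels:
    @pytest.mark.parametrize(
        "alpha, n, expected",
        [(0.05, 120, 0.05 / 120), (0.05, 59, 0.05 / 59), (0.05, 1, 0.05)],
    )
    def test_bonferroni(self, alpha, n, expected):
        assert bonferroni_threshold(alpha, n) == pytest.approx(expected)

    def test_bonferroni_matches_printed_roundings(self):
        assert round(bonferroni_threshold(0.05, 120), 5) == 4.2e-4
        assert round(bonferroni_threshold(0.05, 59), 4) == 0.0008

    def test_bonferroni_invalid_inputs(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(1.5, 10)
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)

    @pytest.mark.parametrize(
        "beta, label",
        [(-0.76, "strong"), (0.2, "moderate"), (0.0, "weak"),
         (0.49, "moderate"), (0.5, "strong"), (-0.19, "weak")],
    )
    def test_effect_size_labels(self, beta, label):
        assert effect_size_label(beta) == label

    def test_effect_size_label_rejects_nan(self):
        with pytest.raises(ValueError):
            effect_size_label(np.nan)


class TestStandardizedBeta:
    def test_equals_pearson_r_in_simple_regression(self, rng):
        x = rng.standard_normal(50)
        y = 0.6 * x + rng.standard_normal(50)
        slope = np.polyfit(x, y, 1)[0]
        assert standardized_beta(slope, x, y) == pytest.approx(
            np.corrcoef(x, y)[0, 1])

    def test_scale_invariance(self, rng):
        x = rng.standard_normal(30)
        y = 2 * x + rng.standard_normal(30)
        slope = np.polyfit(x, y, 1)[0]
        slope10 = np.polyfit(10 * x, y, 1)[0]
        assert standardized_beta(slope, x, y) == pytest.approx(
            standardized_beta(slope10, 10 * x, y))

    def test_matches_refit_on_zscored_data(self, rng):
        X = np.column_stack([rng.standard_normal(60) for _ in range(3)])
        y = X @ [1.0, -0.5, 0.2] + rng.standard_normal(60)
        Xc = np.column_stack([X, np.ones(60)])
        coef = np.linalg.lstsq(Xc, y, rcond=None)[0]
        Xz = (X - X.mean(0)) / X.std(0, ddof=1)
        yz = (y - y.mean()) / y.std(ddof=1)
        coef_z = np.linalg.lstsq(
            np.column_stack([Xz, np.ones(60)]), yz, rcond=None)[0]
        for j in range(3):
            assert standardized_beta(coef[j], X[:, j], y) == pytest.approx(
                coef_z[j], abs=1e-10)

    def test_zero_variance_rejected(self, rng):
        with pytest.raises(ValueError):
            standardized_beta(1.0, np.ones(10), rng.standard_normal(10))


class TestRobustFit:
    def test_exact_linear_data_recovered_with_unit_weights(self, rng):
        X = np.column_stack([rng.standard_normal(20), np.ones(20)])
        y = X @ [2.0, -1.0]
        fit = robust_fit(y, X)
        assert fit.coef == pytest.approx([2.0, -1.0], abs=1e-10)
        assert fit.weights == pytest.approx(np.ones(20))

    def test_gross_outlier_downweighted_to_zero_influence(self):
        # 10-point line plus one gross outlier; slope must track the clean OLS
        rng = np.random.default_rng(5)
        x = np.arange(10, dtype=float)
        y = 1.5 * x + 2 + 0.05 * rng.standard_normal(10)
        y_out = y.copy()
        y_out[9] += 60.0
        X = np.column_stack([x, np.ones(10)])
        fit = robust_fit(y_out, X)
        clean_slope = np.linalg.lstsq(X, y, rcond=None)[0][0]
        assert fit.weights[9] < 0.01
        assert abs(fit.coef[0] - clean_slope) / clean_slope < 0.01

    def test_constant_outcome_gives_flat_fit(self, rng):
        X = np.column_stack([rng.standard_normal(15), np.ones(15)])
        fit = robust_fit(np.full(15, 3.0), X)
        assert fit.coef == pytest.approx([0.0, 3.0], abs=1e-10)

    def test_matches_hand_iterated_irls(self):
        # independent textbook IRLS loop, written from the definition
        rng = np.random.default_rng(5)
        x = np.arange(10, dtype=float)
        y = 1.5 * x + 2 + 0.05 * rng.standard_normal(10)
        y[9] += 60.0
        X = np.column_stack([x, np.ones(10)])
        c = 4.685
        b = np.linalg.lstsq(X, y, rcond=None)[0]
        for _ in range(200):
            r = y - X @ b
            s = np.median(np.abs(r)) / 0.6745
            u = r / (c * s)
            w = np.where(np.abs(u) < 1, (1 - u**2) ** 2, 0.0)
            sw = np.sqrt(w)
            b_new = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)[0]
            if np.max(np.abs(b_new - b)) < 1e-12:
                b = b_new
                break
            b = b_new
        fit = robust_fit(y, X)
        assert fit.coef == pytest.approx(b, abs=1e-8)

    def test_matches_statsmodels_rlm(self, rng):
        X = np.column_stack([rng.standard_normal(40),
                             rng.standard_normal(40), np.ones(40)])
        y = X @ [1.0, -2.0, 0.5] + rng.standard_normal(40)
        y[3] += 12.0
        fit = robust_fit(y, X)
        ref = sm.RLM(y, X, M=sm.robust.norms.TukeyBiweight(4.685)).fit()
        assert fit.coef == pytest.approx(ref.params, abs=1e-4)
        assert fit.t == pytest.approx(ref.tvalues, rel=1e-3)

    def test_rank_deficient_design_rejected(self, rng):
        x = rng.standard_normal(12)
        X = np.column_stack([x, 2 * x, np.ones(12)])
        with pytest.raises(ValueError):
            robust_fit(rng.standard_normal(12), X)


class TestRobustPermutationWald:
    def test_single_ci_wald_is_squared_t(self, rng):
        X = np.column_stack([rng.standard_normal(30),
                             rng.standard_normal(30), np.ones(30)])
        y = 0.8 * X[:, 0] + rng.standard_normal(30)
        res = robust_permutation_wald(y, X, [0], n_permutations=99, seed=1)
        assert abs(res.wald - res.t**2) < 1e-8

    def test_printed_pairs_consistent_with_identity(self):
        # reported t and W pairs from the study obey W = t^2 within rounding
        for t, w in [(-4.49, 20.20), (1.93, 3.74), (-1.50, 2.26)]:
            lo, hi = (abs(t) - 0.005) ** 2, (abs(t) + 0.005) ** 2
            assert lo <= w + 0.005 and w - 0.005 <= hi

    def test_perfect_association_attains_minimum_p(self, rng):
        x = rng.standard_normal(25)
        X = np.column_stack([x, np.ones(25)])
        y = 3.0 * x + 0.01 * rng.standard_normal(25)
        res = robust_permutation_wald(y, X, [0], n_permutations=199, seed=2)
        assert res.p_value == pytest.approx(1 / 200)

    def test_exhaustive_mode_matches_plain_enumeration(self, rng):
        # n=5 : engine enumerates all 120 permutations; oracle is a simple
        # loop over itertools.permutations using the single-fit routine
        n = 5
        x = rng.standard_normal(n)
        X = np.column_stack([x, np.ones(n)])
        y = 1.2 * x + 0.3 * rng.standard_normal(n)
        res = robust_permutation_wald(y, X, [0], n_permutations=120, seed=0)
        x_res = x - x.mean()
        w_null = []
        for perm in itertools.permutations(range(n)):
            Xp = np.column_stack([x_res[list(perm)], np.ones(n)])
            w_null.append(robust_fit(y, Xp).t[0] ** 2)
        w_obs = robust_fit(y, X).t[0] ** 2
        oracle_p = np.mean(np.array(w_null) >= w_obs - 1e-12)
        assert res.p_value == pytest.approx(oracle_p, abs=1e-12)

    def test_two_seeds_agree_within_binomial_error(self, rng):
        X = np.column_stack([rng.standard_normal(40), np.ones(40)])
        y = 0.35 * X[:, 0] + rng.standard_normal(40)
        p = [robust_permutation_wald(y, X, [0], n_permutations=2000,
                                     seed=s).p_value for s in (1, 2)]
        se = np.sqrt(p[0] * (1 - p[0]) / 2000)
        assert abs(p[0] - p[1]) < 3 * se + 1e-9

    def test_residual_scheme_also_calibrated(self, rng):
        rejections = 0
        for rep in range(100):
            local = np.random.default_rng(rep)
            X = np.column_stack([local.standard_normal(30), np.ones(30)])
            y = local.standard_normal(30)
            est = RobustPermutationRegressor(
                ci=[0], n_permutations=99, seed=rep, permute="residuals",
                fit_intercept=False).fit(X, y)
            rejections += est.result_.p_value < 0.05
        # binomial 95% band for 100 draws at alpha = 0.05
        assert 1 <= rejections <= 11

    def test_power_monotone_in_effect_size(self):
        rates = []
        for effect in (0.0, 0.5, 1.0):
            rej = 0
            for rep in range(40):
                local = np.random.default_rng(1000 + rep)
                x = local.standard_normal(35)
                X = np.column_stack([x, np.ones(35)])
                y = effect * x + local.standard_normal(35)
                res = robust_permutation_wald(y, X, [0], n_permutations=199,
                                              seed=rep)
                rej += res.p_value < 0.05
            rates.append(rej / 40)
        assert rates[0] <= rates[1] <= rates[2]
        assert rates[2] > rates[0]


class TestRepeatedMeasuresLMM:
    def test_stage_t_equals_paired_t_without_covariates(self):
        df = make_long_repeated(20, seed=3, stage_effect=1.5)
        fit = fit_lmm_repeated(df.assign(group=0.0), "y")
        wide = df.pivot(index="participant", columns="stage", values="y")
        oracle = stats.ttest_rel(wide[1.0], wide[0.0]).statistic
        assert fit.coef_table().loc["stage", "t"] == pytest.approx(
            oracle, abs=1e-6)

    def test_zero_outcome_gives_zero_coefficients(self):
        df = make_long_repeated(12, seed=1)
        df["y"] = 0.0
        fit = fit_lmm_repeated(df, "y")
        assert fit.coef == pytest.approx(np.zeros(len(fit.coef)), abs=1e-10)

    def test_matches_statsmodels_mixedlm(self):
        df = make_long_repeated(25, seed=9, stage_effect=1.0,
                                group_effect=-0.5, interaction_effect=0.8,
                                with_covariates=True)
        fit = fit_lmm_repeated(df, "y", cni=("age",))
        df = df.assign(inter=df.stage * df.group)
        ref = smf.mixedlm("y ~ stage + group + inter + age", df,
                          groups=df.participant).fit(reml=True)
        mine = fit.coef_table()
        for name, ref_name in [("stage", "stage"), ("group", "group"),
                               ("interaction", "inter"), ("age", "age")]:
            assert mine.loc[name, "coef"] == pytest.approx(
                ref.params[ref_name], abs=1e-5)
            assert mine.loc[name, "t"] == pytest.approx(
                ref.tvalues[ref_name], abs=1e-4)

    def test_recovers_simulated_stage_effect(self):
        estimates = [
            fit_lmm_repeated(
                make_long_repeated(40, seed=s, stage_effect=2.0), "y"
            ).coef_table().loc["stage", "coef"]
            for s in range(60)
        ]
        mean = np.mean(estimates)
        se = np.std(estimates, ddof=1) / np.sqrt(len(estimates))
        assert abs(mean - 2.0) < 3 * se + 0.05

    def test_unbalanced_subjects_rejected(self):
        df = make_long_repeated(6, seed=0).iloc[:-1]
        with pytest.raises(ValueError):
            fit_lmm_repeated(df, "y")

    def test_exhaustive_sign_flip_matches_enumeration_oracle(self):
        # n=6 subjects: all 64 within-subject stage flips enumerated; the
        # oracle recomputes the paired t for every flip pattern directly
        df = make_long_repeated(6, seed=11, stage_effect=1.8, noise_sd=1.0)
        df["group"] = 0.0
        results = permutation_p_lmm(df, "y", n_permutations=64,
                                    ci=("stage",), seed=0)
        diffs = (df[df.stage == 1].sort_values("participant")["y"].to_numpy()
                 - df[df.stage == 0].sort_values("participant")["y"].to_numpy())
        t_obs = diffs.mean() / (diffs.std(ddof=1) / np.sqrt(6))
        t_null = []
        for signs in itertools.product([1, -1], repeat=6):
            d = diffs * signs
            t_null.append(d.mean() / (d.std(ddof=1) / np.sqrt(6)))
        oracle_p = np.mean(np.abs(t_null) >= abs(t_obs) - 1e-12)
        assert results["stage"].p_value == pytest.approx(oracle_p, abs=1e-12)
        assert results["stage"].n_permutations == 64

    def test_exhaustive_p_is_seed_independent(self):
        df = make_long_repeated(5, seed=2, stage_effect=1.0)
        df["group"] = 0.0
        p = [permutation_p_lmm(df, "y", n_permutations=32, ci=("stage",),
                               seed=s)["stage"].p_value for s in (1, 99)]
        assert p[0] == p[1]

    def test_interaction_test_calibrated_under_stage_effect(self):
        # null for the interaction, with a real stage main effect present
        rejections = 0
        for rep in range(100):
            df = make_long_repeated(16, seed=3000 + rep, stage_effect=2.0,
                                    group_effect=1.0)
            res = permutation_p_lmm(df, "y", n_permutations=99,
                                    ci=("interaction",), seed=rep)
            rejections += res["interaction"].p_value < 0.05
        assert 1 <= rejections <= 11

    def test_group_test_calibrated(self):
        rejections = 0
        for rep in range(100):
            df = make_long_repeated(16, seed=5000 + rep, stage_effect=1.0)
            res = permutation_p_lmm(df, "y", n_permutations=99,
                                    ci=("group",), seed=rep)
            rejections += res["group"].p_value < 0.05
        assert 1 <= rejections <= 11

    def test_detects_planted_interaction(self):
        df = make_long_repeated(40, seed=77, stage_effect=1.0,
                                interaction_effect=3.0, noise_sd=1.0)
        res = permutation_p_lmm(df, "y", n_permutations=499, seed=0)
        assert res["interaction"].p_value < 0.01
        assert res["interaction"].coefficient == pytest.approx(3.0, abs=1.0)
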