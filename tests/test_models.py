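"""Statistical layer: elementary statistics, the random-intercept model
(checked against statsmodels MixedLM), forward selection, learning-rate
regression, residual summaries."""
import warnings

import numpy as np
import pandas as pd
import pytest
import scipy.stats
import statsmodels.api as sm

from surgskill.models import (ForwardSelectCV, LearningRateModel,
                              RandomInterceptRegressor,
                              build_learning_rate_records, efron_pseudo_r2,
                              error_metrics, fit_learning_rate_model,
                              fit_random_intercept, forward_select_cv,
                              learning_rate, pearson,
                              prediction_residual_summary, surg_tlx_total)


class TestLearningRate:
    def test_hand_examples(self):
        assert learning_rate([60, 70, 80]) == pytest.approx(10.0)
        assert learning_rate([70, 70]) == 0.0

    def test_matches_closed_form_oracle(self, rng):
        for _ in range(20):
            y = rng.uniform(0, 100, rng.integers(2, 8))
            x = np.arange(1, len(y) + 1)
            oracle = ((x - x.mean()) @ (y - y.mean())
                      / ((x - x.mean()) ** 2).sum())
            assert learning_rate(y) == pytest.approx(oracle, abs=1e-12)

    def test_single_attempt_rejected(self):
        with pytest.raises(ValueError):
            learning_rate([50])


class TestSurgTlx:
    def test_bounds(self):
        assert surg_tlx_total([1] * 6) == 6
        assert surg_tlx_total([20] * 6) == 120

    def test_arithmetic(self):
        assert surg_tlx_total((3, 5, 7, 2, 9, 4)) == 30

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            surg_tlx_total([0, 5, 5, 5, 5, 5])
        with pytest.raises(ValueError):
            surg_tlx_total([5] * 5)


class TestFitStatistics:
    def test_efron_extremes(self, rng):
        y = rng.uniform(0, 100, 30)
        assert efron_pseudo_r2(y, y) == pytest.approx(1.0)
        assert efron_pseudo_r2(y, np.full(30, y.mean())) == pytest.approx(0.0)
        worse = np.full(30, y.mean() + 3 * y.std())
        assert efron_pseudo_r2(y, worse) < 0

    def test_efron_constant_outcome_flagged(self):
        with pytest.warns(UserWarning, match="undefined"):
            assert np.isnan(efron_pseudo_r2([3, 3, 3], [3, 2, 3]))

    def test_error_metric_examples(self):
        y = np.zeros(2)
        assert error_metrics(y, [1, -1]) == (1.0, 1.0)
        mae, rmse = error_metrics(y, [3, -4])
        assert mae == 3.5
        assert rmse == pytest.approx(np.sqrt(12.5))

    def test_rmse_dominates_mae(self, rng):
        for _ in range(10):
            y = rng.normal(size=20)
            yh = rng.normal(size=20)
            mae, rmse = error_metrics(y, yh)
            assert rmse >= mae - 1e-12


class TestPearson:
    def test_perfect_correlations(self, rng):
        x = rng.normal(size=20)
        r, p = pearson(x, 3 * x + 1)
        assert r == pytest.approx(1.0)
        r, _ = pearson(x, -x)
        assert r == pytest.approx(-1.0)

    def test_zero_variance_flagged(self):
        with pytest.warns(UserWarning, match="zero variance"):
            r, p = pearson(np.ones(5), np.arange(5))
        assert np.isnan(r)

    def test_type_one_error_near_nominal(self, rng):
        hits = sum(pearson(rng.normal(size=26),
                           rng.normal(size=26))[1] < 0.05
                   for _ in range(2000))
        assert abs(hits / 2000 - 0.05) < 0.015


def simulate_ri(rng, n_subj=26, per=3, betas=(-8.0, 0.5), sd_u=5.0,
                sd_e=5.0, intercept=70.0):
    groups = np.repeat(np.arange(n_subj), per)
    X = rng.standard_normal((len(groups), len(betas)))
    u = rng.normal(0, sd_u, n_subj) if sd_u > 0 else np.zeros(n_subj)
    eps = rng.normal(0, sd_e, len(groups)) if sd_e > 0 else 0.0
    y = intercept + X @ np.array(betas) + u[groups] + eps
    return pd.DataFrame(X, columns=[f"x{i}" for i in range(len(betas))]), \
        y, groups


class TestRandomInterceptRegressor:
    def test_matches_statsmodels_mixedlm_ml(self, rng):
        X, y, groups = simulate_ri(rng)
        ours = RandomInterceptRegressor().fit(X, y, groups)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ref = sm.MixedLM(y, sm.add_constant(X.to_numpy()),
                             groups=groups).fit(reml=False)
        assert np.allclose(np.r_[ours.intercept_, ours.coef_],
                           ref.fe_params, atol=1e-4)
        assert np.allclose(ours.se_, ref.bse_fe, atol=2e-2)
        assert ours.sigma2_e_ == pytest.approx(ref.scale, rel=1e-3)
        assert ours.sigma2_u_ == pytest.approx(
            float(np.asarray(ref.cov_re)[0, 0]), rel=1e-3, abs=1e-6)
        assert ours.loglik_ == pytest.approx(ref.llf, abs=1e-6)

    def test_noiseless_fixed_effects_recovered_exactly(self, rng):
        X, y, groups = simulate_ri(rng, sd_u=0.0, sd_e=0.0)
        m = RandomInterceptRegressor().fit(X, y, groups)
        assert np.allclose(m.coef_, [-8.0, 0.5], atol=1e-6)
        assert m.intercept_ == pytest.approx(70.0, abs=1e-6)

    def test_no_random_effect_detected_when_absent(self, rng):
        nonsig = 0
        for _ in range(20):
            X, y, groups = simulate_ri(rng, sd_u=0.0, sd_e=5.0)
            m = RandomInterceptRegressor().fit(X, y, groups)
            nonsig += m.random_effect_pvalue_ >= 0.05
        assert nonsig >= 18

    def test_random_effect_detected_when_strong(self, rng):
        X, y, groups = simulate_ri(rng, sd_u=10.0, sd_e=3.0)
        m = RandomInterceptRegressor().fit(X, y, groups)
        assert m.random_effect_pvalue_ < 0.01

    def test_blup_prediction_shrinks_toward_subject(self, rng):
        X, y, groups = simulate_ri(rng, sd_u=10.0)
        m = RandomInterceptRegressor().fit(X, y, groups)
        pop = m.predict(X)
        subj = m.predict(X, groups=groups)
        assert np.mean((y - subj) ** 2) < np.mean((y - pop) ** 2)

    def test_summary_schema(self, rng):
        X, y, groups = simulate_ri(rng)
        fit = fit_random_intercept(y, X, groups)
        assert list(fit.params.columns) == ["estimate", "se", "p"]
        assert fit.n == len(y)
        assert (fit.params["se"] > 0).all()
        assert fit.params["p"].between(0, 1).all()
        assert fit.rmse >= fit.mae

    def test_collinear_design_rejected(self, rng):
        X, y, groups = simulate_ri(rng)
        X["x2"] = 2 * X["x0"]
        with pytest.raises(ValueError, match="collinear"):
            RandomInterceptRegressor().fit(X, y, groups)

    def test_single_group_rejected(self, rng):
        X, y, groups = simulate_ri(rng, n_subj=1, per=10)
        with pytest.raises(ValueError):
            RandomInterceptRegressor().fit(X, y, groups)


class TestForwardSelectCV:
    def make_problem(self, rng, beta=10.0, K=40):
        groups = np.repeat(np.arange(26), 3)
        F = rng.standard_normal((len(groups), K))
        u = rng.normal(0, 5, 26)
        y = 70 + beta * F[:, 0] + u[groups] + rng.normal(0, 5, len(groups))
        X = pd.DataFrame(F, columns=[f"f{i:03d}" for i in range(K)])
        return X, y, groups

    def test_planted_feature_found_in_every_fold(self, rng):
        X, y, groups = self.make_problem(rng)
        sel = ForwardSelectCV(k=7, random_state=0).fit(X, y, groups)
        assert "f000" in sel.selected_features_
        assert sum("f000" in v for v in sel.fold_selections_.values()) >= 6

    def test_deterministic_given_seed(self, rng):
        X, y, groups = self.make_problem(rng)
        a = forward_select_cv(X, y, groups, random_state=3)
        b = forward_select_cv(X, y, groups, random_state=3)
        assert a == b
        sel = ForwardSelectCV(k=7, random_state=3).fit(X, y, groups)
        assert set(sel.fold_assignments_) == set(np.unique(groups))

    def test_selection_only_from_input_columns(self, rng):
        X, y, groups = self.make_problem(rng)
        sel = forward_select_cv(X, y, groups)
        assert set(sel) <= set(X.columns)

    def test_invariant_to_column_order(self, rng):
        X, y, groups = self.make_problem(rng)
        a = forward_select_cv(X, y, groups, random_state=1)
        b = forward_select_cv(X[list(reversed(X.columns))], y, groups,
                              random_state=1)
        assert a == b

    def test_grid_profile_matches_fine_grid_oracle(self, rng):
        from surgskill.models import (_LAMBDA_GRID, _forward_select_single,
                                      _group_codes)
        fine = np.concatenate([[0.0], np.logspace(-5.0, 5.0, 301)])
        for seed in range(5):
            r = np.random.default_rng(seed)
            X, y, groups = self.make_problem(r, K=15)
            codes, _, counts = _group_codes(groups)
            names = list(X.columns)
            a = _forward_select_single(X.to_numpy(), y, codes, counts,
                                       names, 0.05, 5)
            b = _forward_select_single(X.to_numpy(), y, codes, counts,
                                       names, 0.05, 5, grid=fine)
            assert a == b

    def test_final_estimator_fitted_on_selection(self, rng):
        X, y, groups = self.make_problem(rng)
        sel = ForwardSelectCV(k=7, random_state=0).fit(X, y, groups)
        assert sel.estimator_ is not None
        assert sel.estimator_.feature_names_ == sel.selected_features_

    def test_too_many_folds_rejected(self, rng):
        X, y, groups = self.make_problem(rng)
        with pytest.raises(ValueError, match="folds"):
            ForwardSelectCV(k=30).fit(X, y, groups)

    def test_missing_values_rejected(self, rng):
        X, y, groups = self.make_problem(rng)
        X.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            ForwardSelectCV().fit(X, y, groups)


class TestLearningRateModel:
    def make_records(self, rng, noise=0.5, n=26):
        base = rng.uniform(40, 95, n)
        f1 = rng.standard_normal(n)
        slope = 5.0 - 0.35 * base + 2.0 * f1
        if noise:
            slope = slope + rng.normal(0, noise, n)
        return pd.DataFrame({"baseline_score": base, "feat_a": f1,
                             "age": rng.uniform(20, 70, n),
                             "noise_1": rng.standard_normal(n),
                             "slope": slope})

    def test_noiseless_fit_is_exact(self, rng):
        df = self.make_records(rng, noise=0.0)
        fit = fit_learning_rate_model(df, ["feat_a", "noise_1"])
        assert fit.r2 == pytest.approx(1.0, abs=1e-9)
        assert fit.params.loc["baseline_score", "estimate"] == \
            pytest.approx(-0.35, abs=1e-8)

    def test_baseline_coefficient_recovered_within_2se(self, rng):
        hits = 0
        for _ in range(40):
            df = self.make_records(rng, noise=1.0)
            fit = fit_learning_rate_model(df, ["feat_a", "noise_1"])
            est = fit.params.loc["baseline_score", "estimate"]
            se = fit.params.loc["baseline_score", "se"]
            hits += abs(est - (-0.35)) <= 2 * se
        assert hits >= 36

    def test_summary_schema_matches_coefficient_table_layout(self, rng):
        fit = fit_learning_rate_model(self.make_records(rng),
                                      ["feat_a", "noise_1"])
        assert list(fit.params.columns) == ["estimate", "se", "p"]
        assert {"r2", "mae", "rmse", "n"} <= set(vars(fit))

    def test_baseline_always_included(self, rng):
        df = self.make_records(rng)
        m = LearningRateModel().fit(df[["baseline_score", "feat_a",
                                        "noise_1", "age"]],
                                    df["slope"].to_numpy())
        assert "baseline_score" in m.columns_

    def test_build_records_from_attempt_table(self):
        table = pd.DataFrame({
            "subject": [1, 1, 1, 2, 2],
            "task": ["Tubes"] * 5,
            "attempt": [1, 2, 3, 1, 2],
            "score": [60.0, 70.0, 80.0, 50.0, 50.0],
            "age": [30] * 3 + [40] * 2,
            "f": [0.1, 0.9, 0.9, 0.4, 0.8],
        })
        rec = build_learning_rate_records(table, ["f"])
        assert len(rec) == 2
        r1 = rec[rec.subject == 1].iloc[0]
        assert r1["slope"] == pytest.approx(10.0)
        assert r1["baseline_score"] == 60.0
        assert r1["f"] == 0.1          # first attempt only


class TestResidualSummary:
    def test_perfect_predictions_summarize_to_zero(self):
        y = np.arange(10.0)
        out = prediction_residual_summary(y, y, ["Tubes"] * 10)
        row = out.loc["Tubes"]
        assert row["median"] == row["mean"] == row["iqr"] == 0.0
        assert row["outliers"] == []

    def test_hand_example(self):
        res = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
        out = prediction_residual_summary(res, np.zeros(5), ["T"] * 5)
        assert out.loc["T", "median"] == 0.0
        assert out.loc["T", "iqr"] == 2.0

    def test_whisker_rule_matches_quantile_oracle(self, rng):
        pred = rng.normal(size=200)
        actual = np.zeros(200)
        out = prediction_residual_summary(pred, actual, ["T"] * 200)
        r = pred
        q1, q3 = np.percentile(r, [25, 75])
        iqr = q3 - q1
        inside = r[(r >= q1 - 1.5 * iqr) & (r <= q3 + 1.5 * iqr)]
        assert out.loc["T", "whisker_low"] == inside.min()
        assert out.loc["T", "whisker_high"] == inside.max()
        assert sorted(out.loc["T", "outliers"]) == sorted(
            r[(r < q1 - 1.5 * iqr) | (r > q3 + 1.5 * iqr)].tolist())
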