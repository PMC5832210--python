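import numpy as np
import pandas as pd
import pytest

import _oracles as orc
from nodal_petrad.survival import (aic, aic_ordering, check_log_linearity,
                                   check_ph_schoenfeld, concordance_index,
                                   external_validate, lasso_cox_cv,
                                   log_partial_likelihood,
                                   pearson_correlation_matrix, refit_cox,
                                   univariable_cox)
from nodal_petrad.synthetic import SurvivalSpec, simulate_survival


def _cohort(n, beta, censoring, seed, p_noise=0):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame({"x": rng.normal(size=n)})
    for j in range(p_noise):
        X[f"noise{j}"] = rng.normal(size=n)
    spec = SurvivalSpec(n_patients=n, betas={"x": beta} if beta else {},
                        censoring_rate=censoring, seed=seed + 1)
    t, d = simulate_survival({c: X[c].to_numpy() for c in X.columns}, spec)
    return X, t, d


class TestConcordance:
    @pytest.mark.parametrize("seed,censor", [(0, 0.0), (1, 0.3), (2, 0.5), (3, 0.3)])
    def test_equals_bruteforce_all_pairs(self, seed, censor):
        rng = np.random.default_rng(seed)
        n = 25
        t = rng.exponential(size=n)
        d = (rng.random(n) > censor).astype(int)
        r = np.round(rng.normal(size=n), 1)  # rounding forces some risk ties
        res = concordance_index(r, t, d)
        assert res.c == pytest.approx(orc.concordance_oracle(r, t, d), abs=1e-14)

    def test_perfect_ranking_is_one(self):
        t = np.array([5.0, 4.0, 3.0, 2.0, 1.0])
        r = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        res = concordance_index(r, t, np.ones(5))
        assert res.c == 1.0

    def test_all_tied_risks_half(self):
        rng = np.random.default_rng(4)
        res = concordance_index(np.ones(50), rng.exponential(size=50),
                                np.ones(50))
        assert res.c == 0.5

    def test_random_scores_near_half_large_n(self):
        rng = np.random.default_rng(5)
        n = 2000
        _, t, d = _cohort(n, 0.0, 0.3, seed=6)
        res = concordance_index(rng.normal(size=n), t, d)
        assert abs(res.c - 0.5) < 0.02
        assert res.ci_low < 0.5 < res.ci_high

    def test_matches_lifelines_on_continuous_data(self):
        from lifelines.utils import concordance_index as ll_c
        rng = np.random.default_rng(7)
        n = 300
        t = rng.exponential(size=n)
        d = (rng.random(n) > 0.3).astype(int)
        r = rng.normal(size=n)
        ours = concordance_index(r, t, d).c
        theirs = ll_c(t, -r, d)  # lifelines scores low predictions as high risk
        assert ours == pytest.approx(theirs, abs=1e-12)

    def test_ci_methods_agree_roughly(self):
        _, t, d = _cohort(400, 0.4, 0.3, seed=8)
        r = np.random.default_rng(9).normal(size=400) + 0.3 * np.arange(400) / 400
        jk = concordance_index(r, t, d, ci_method="jackknife")
        bs = concordance_index(r, t, d, ci_method="bootstrap", seed=1)
        assert jk.ci_high - jk.ci_low == pytest.approx(bs.ci_high - bs.ci_low,
                                                      rel=0.5)

    def test_no_comparable_pairs_errors(self):
        with pytest.raises(ValueError):
            concordance_index([1.0, 2.0], [1.0, 2.0], [0, 0])


class TestUnivariableCox:
    def test_null_feature(self):
        X, t, d = _cohort(1000, 0.0, 0.3, seed=10)
        res = univariable_cox(X["x"], t, d, name="x")
        assert 0.9 < res.hr < 1.1
        assert abs(res.c - 0.5) < 0.03
        assert res.hr_ci_low < res.hr < res.hr_ci_high

    def test_parameter_recovery(self):
        X, t, d = _cohort(2000, np.log(1.5), 0.3, seed=11)
        res = univariable_cox(X["x"], t, d, name="x")
        # x is standard normal, so the per-unit HR is the per-SD HR
        assert 1.35 < res.hr < 1.65
        assert res.p < 1e-6

    def test_constant_feature_errors(self):
        _, t, d = _cohort(100, 0.0, 0.0, seed=12)
        with pytest.raises(ValueError):
            univariable_cox(np.ones(100), t, d)

    def test_scaling_transforms_hr(self):
        X, t, d = _cohort(500, 0.5, 0.2, seed=13)
        r1 = univariable_cox(X["x"], t, d)
        r2 = univariable_cox(X["x"] * 4.0, t, d)
        assert r2.hr ** 4.0 == pytest.approx(r1.hr, rel=1e-4)


class TestPearson:
    def test_linear_and_independent(self):
        rng = np.random.default_rng(14)
        x = rng.normal(size=500)
        df = pd.DataFrame({"x": x, "x2": 2 * x, "z": rng.normal(size=500)})
        corr = pearson_correlation_matrix(df)
        assert corr.loc["x", "x2"] == pytest.approx(1.0)
        assert abs(corr.loc["x", "z"]) < 0.1
        np.testing.assert_allclose(corr.values, corr.values.T)
        np.testing.assert_allclose(np.diag(corr.values), 1.0)

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError):
            pearson_correlation_matrix(pd.DataFrame({"a": [1, 1, 1],
                                                     "b": [1, 2, 3]}))


class TestLassoCox:
    def test_planted_feature_selected(self):
        X, t, d = _cohort(260, np.log(2), 0.4, seed=15, p_noise=20)
        res = lasso_cox_cv(X, t, d, n_folds=10, seed=0)
        assert "x" in res.selected

    def test_full_shrinkage_empty_selection(self):
        X, t, d = _cohort(100, np.log(2), 0.2, seed=16, p_noise=3)
        res = lasso_cox_cv(X, t, d, seed=0, alphas=[1e4])
        assert res.selected == []
        assert res.coef == {}

    def test_duplicated_columns_no_opposite_signs(self):
        X, t, d = _cohort(200, np.log(1.8), 0.2, seed=17, p_noise=2)
        X["x_copy"] = X["x"].to_numpy()
        res = lasso_cox_cv(X, t, d, seed=3)
        if "x" in res.coef and "x_copy" in res.coef:
            assert np.sign(res.coef["x"]) == np.sign(res.coef["x_copy"])

    def test_reproducible_with_seed(self):
        X, t, d = _cohort(150, 0.6, 0.3, seed=18, p_noise=5)
        r1 = lasso_cox_cv(X, t, d, seed=11)
        r2 = lasso_cox_cv(X, t, d, seed=11)
        assert r1.selected == r2.selected
        assert r1.alpha == r2.alpha
        assert r1.coef == r2.coef

    def test_too_few_events_errors(self):
        X, t, d = _cohort(30, 0.0, 0.9, seed=19)
        with pytest.raises(ValueError):
            lasso_cox_cv(X, t, d, n_folds=10, seed=0)


class TestRefit:
    def test_single_feature_matches_univariable(self):
        X, t, d = _cohort(300, 0.5, 0.3, seed=20)
        uni = univariable_cox(X["x"], t, d, name="x")
        fit = refit_cox(X, t, d, ["x"])
        assert fit.hr["x"] == pytest.approx(uni.hr, abs=1e-8)
        assert fit.aic == pytest.approx(2 * 1 - 2 * fit.log_partial_likelihood)

    def test_empty_selection_errors(self):
        X, t, d = _cohort(50, 0.0, 0.0, seed=21)
        with pytest.raises(ValueError):
            refit_cox(X, t, d, [])


class TestAIC:
    def test_direct_formula(self):
        assert aic(0.0, 2) == 4.0

    def test_penalty_monotone_in_k(self):
        assert aic(-100.0, 1) < aic(-100.0, 3)

    def test_ordering_ascending(self):
        assert aic_ordering({"a": 10.0, "b": 5.0, "c": 7.5}) == ["b", "c", "a"]

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            aic(np.nan, 1)


class TestLogPartialLikelihood:
    def test_matches_lifelines(self):
        from lifelines import CoxPHFitter
        X, t, d = _cohort(200, 0.7, 0.3, seed=22)
        df = X.copy()
        df["time"], df["event"] = t, d
        cph = CoxPHFitter().fit(df, "time", "event")
        ours = log_partial_likelihood(X["x"] * cph.params_["x"], t, d)
        # continuous times: Breslow and Efron coincide (no ties)
        assert ours == pytest.approx(cph.log_likelihood_, rel=1e-6)


class TestDiagnostics:
    def test_linear_effect_verdict(self):
        hits = 0
        for rep in range(8):
            X, t, d = _cohort(400, 0.6, 0.2, seed=100 + rep)
            out = check_log_linearity(X["x"].to_numpy(), t, d)
            hits += out["verdict"] == "log-linear"
        assert hits >= 6

    def test_log_shaped_effect_flagged_and_log_recommended(self):
        hits_nonlin, hits_rec = 0, 0
        for rep in range(8):
            rng = np.random.default_rng(200 + rep)
            vol = rng.lognormal(2.0, 1.2, size=500)
            spec = SurvivalSpec(n_patients=500, betas={"lv": 1.2},
                                censoring_rate=0.2, seed=300 + rep)
            t, d = simulate_survival({"lv": np.log(vol)}, spec)
            out = check_log_linearity(vol, t, d, name="volume")
            hits_nonlin += out["verdict"] == "non-linear"
            hits_rec += out["recommend_log_transform"]
        assert hits_nonlin >= 6
        assert hits_rec >= 5

    def test_zero_effect_verdict_linear(self):
        X, t, d = _cohort(400, 0.0, 0.2, seed=23)
        out = check_log_linearity(X["x"].to_numpy(), t, d)
        assert out["verdict"] == "log-linear"

    def test_ph_holds_for_proportional_simulation(self):
        hits = 0
        for rep in range(6):
            X, t, d = _cohort(300, 0.6, 0.2, seed=400 + rep)
            out = check_ph_schoenfeld(X, t, d, ["x"])
            hits += out["p_values"]["x"] > 0.05
        assert hits >= 5

    def test_ph_violated_for_reversing_effect(self):
        hits = 0
        for rep in range(6):
            rng = np.random.default_rng(500 + rep)
            n = 400
            x = rng.normal(size=n)
            # effect reverses sign at the median event time
            t0 = rng.exponential(np.exp(-1.2 * x))
            med = np.median(t0)
            t = np.where(t0 < med, t0, med + rng.exponential(np.exp(1.2 * x)))
            d = np.ones(n, dtype=int)
            out = check_ph_schoenfeld(pd.DataFrame({"x": x}), t, d, ["x"])
            hits += out["p_values"]["x"] < 0.05
        assert hits >= 5

    def test_single_event_errors(self):
        X = pd.DataFrame({"x": np.random.default_rng(0).normal(size=20)})
        t = np.linspace(1, 20, 20)
        d = np.r_[1, np.zeros(19)].astype(int)
        with pytest.raises(ValueError):
            check_ph_schoenfeld(X, t, d, ["x"])


class TestExternalValidation:
    def test_same_cohort_reproduces_internal_c(self):
        X, t, d = _cohort(300, 0.7, 0.3, seed=24)
        fit = refit_cox(X, t, d, ["x"])
        res = external_validate(fit, X, t, d)
        assert res.c == pytest.approx(fit.c_internal, abs=1e-12)

    def test_permuted_outcome_near_half(self):
        X, t, d = _cohort(500, 0.8, 0.2, seed=25)
        fit = refit_cox(X, t, d, ["x"])
        rng = np.random.default_rng(26)
        perm = rng.permutation(500)
        res = external_validate(fit, X, t[perm], d[perm])
        assert abs(res.c - 0.5) < 0.05

    def test_missing_feature_errors(self):
        X, t, d = _cohort(100, 0.5, 0.2, seed=27)
        fit = refit_cox(X, t, d, ["x"])
        with pytest.raises(KeyError):
            external_validate(fit, pd.DataFrame({"y": np.zeros(100)}), t, d)
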