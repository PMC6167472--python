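"""Logistic fitting, stepwise selection, AUROC/Youden oracles, repeated CV."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.special import expit, logit
from scipy.stats import chi2

from tbivitals.modeling import (
    MODEL_SPECS,
    _irls_wald_p,
    auroc,
    fit_logistic,
    mortality_model,
    ppg15_probability,
    repeated_cv,
    stepwise_select,
    stratified_fold_indices,
    youden_operating_point,
)
from tbivitals.synthetic import simulate_binormal_scores
from tbivitals.types import InputError, ParameterError


def brute_force_auroc(scores, labels):
    """Exhaustive pairwise comparison oracle (ties count one half)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestFitLogistic:
    def test_two_by_two_odds_ratio(self):
        # a=20, b=10, c=10, d=20 -> coefficient ln(ad/bc) = ln 4
        y = np.array([1] * 20 + [0] * 10 + [1] * 10 + [0] * 20)
        x = np.array([1] * 30 + [0] * 30)
        fit = fit_logistic(pd.DataFrame({"x": x}), y)
        assert fit.coefficients["x"] == pytest.approx(np.log(4.0), abs=1e-6)

    def test_null_coefficients_small(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.standard_normal((10**4, 3)), columns=list("abc"))
        y = (rng.uniform(size=10**4) < 0.3).astype(int)
        fit = fit_logistic(X, y)
        for v in "abc":
            assert abs(fit.coefficients[v]) < 3 * fit.standard_errors[v]

    def test_intercept_only_equals_logit_prevalence(self):
        y = np.array([1] * 17 + [0] * 83)
        fit = fit_logistic(pd.DataFrame(index=range(100)), y)
        assert fit.intercept == pytest.approx(logit(0.17), abs=1e-6)

    def test_separation_flagged(self):
        y = np.array([0] * 20 + [1] * 20)
        x = np.arange(40.0)
        fit = fit_logistic(pd.DataFrame({"x": x}), y)
        assert fit.separation

    def test_single_class_raises(self):
        with pytest.raises(InputError):
            fit_logistic(pd.DataFrame({"x": [1.0, 2.0]}), np.array([1, 1]))

    def test_wald_chi2_consistency(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame({"x": rng.standard_normal(500)})
        y = (rng.uniform(size=500) < expit(X["x"])).astype(int)
        fit = fit_logistic(X, y)
        w = (fit.coefficients["x"] / fit.standard_errors["x"]) ** 2
        assert fit.wald_chi2["x"] == pytest.approx(w)
        assert w >= 0

    def test_irls_fast_path_matches_statsmodels(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((400, 3))
        y = (rng.uniform(size=400) < expit(X[:, 0] - 0.5 * X[:, 2])).astype(int)
        ref = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
        theirs = chi2.sf((ref.params[1:] / ref.bse[1:]) ** 2, 1)
        np.testing.assert_allclose(_irls_wald_p(X, y), theirs, atol=1e-12)


class TestStepwise:
    def test_true_predictor_recovered(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.standard_normal((2000, 10)), columns=[f"x{i}" for i in range(10)])
        y = (rng.uniform(size=2000) < expit(2.0 * X["x0"])).astype(int)
        fit = stepwise_select(X, y)
        assert "x0" in fit.variables

    def test_all_noise_selects_few(self):
        hits = []
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            X = pd.DataFrame(rng.standard_normal((2000, 10)), columns=[f"x{i}" for i in range(10)])
            y = (rng.uniform(size=2000) < 0.3).astype(int)
            hits.append(len(stepwise_select(X, y).variables))
        assert np.mean(np.array(hits) <= 2) >= 0.9

    def test_empty_candidates_intercept_only(self):
        y = np.array([0, 1] * 20)
        fit = stepwise_select(pd.DataFrame(index=range(40)), y)
        assert fit.variables == []
        assert fit.intercept == pytest.approx(0.0, abs=1e-9)

    def test_p_enter_must_not_exceed_p_remove(self):
        with pytest.raises(ParameterError):
            stepwise_select(pd.DataFrame({"x": [0.0, 1.0]}), np.array([0, 1]), p_enter=0.2, p_remove=0.1)


class TestAUROC:
    def test_known_value(self):
        assert auroc(np.array([0.1, 0.4, 0.35, 0.8]), np.array([0, 0, 1, 1])) == 0.75

    def test_perfect_separation(self):
        assert auroc(np.array([1, 2, 3, 4.0]), np.array([0, 0, 1, 1])) == 1.0

    def test_all_ties_give_half(self):
        assert auroc(np.full(10, 0.5), np.array([0, 1] * 5)) == 0.5

    def test_single_class_raises(self):
        with pytest.raises(InputError):
            auroc(np.array([0.1, 0.2]), np.array([1, 1]))

    def test_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(200):
            n = rng.integers(4, 50)
            scores = np.round(rng.uniform(size=n), 2)  # induce ties
            labels = rng.integers(0, 2, n)
            if labels.sum() in (0, n):
                continue
            assert auroc(scores, labels) == pytest.approx(brute_force_auroc(scores, labels), abs=1e-12)


class TestYouden:
    @staticmethod
    def brute_force(scores, labels):
        best = (-np.inf, None)
        for thr in np.unique(scores):
            pred = scores >= thr
            sens = (pred & (labels == 1)).sum() / (labels == 1).sum()
            spec = (~pred & (labels == 0)).sum() / (labels == 0).sum()
            j = sens + spec - 1
            if j > best[0] + 1e-12:
                best = (j, thr)
        return best

    def test_perfect_separation(self):
        op = youden_operating_point(np.array([1, 2, 3, 4.0]), np.array([0, 0, 1, 1]))
        assert op["sensitivity"] == op["specificity"] == op["ppv"] == op["npv"] == 1.0

    def test_matches_brute_force(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            n = int(rng.integers(6, 40))
            scores = np.round(rng.uniform(size=n), 2)
            labels = rng.integers(0, 2, n)
            if labels.sum() in (0, n):
                continue
            op = youden_operating_point(scores, labels)
            j_ref, thr_ref = self.brute_force(scores, labels)
            assert op["sensitivity"] + op["specificity"] - 1 == pytest.approx(j_ref, abs=1e-12)
            assert op["threshold"] == thr_ref

    def test_null_scores_low_j(self):
        rng = np.random.default_rng(6)
        scores = rng.uniform(size=10**4)
        labels = rng.integers(0, 2, 10**4)
        op = youden_operating_point(scores, labels)
        assert op["sensitivity"] + op["specificity"] - 1 < 0.1


class TestRepeatedCV:
    def _binormal_df(self, n=600, seed=7):
        scores, labels = simulate_binormal_scores(n, 0.80, 0.3, seed=seed)
        return pd.DataFrame({"score": scores, "y": labels})

    def test_deterministic_under_seed(self):
        df = self._binormal_df()
        a = repeated_cv(df, "y", ["score"], k=5, repeats=3, seed=9, selection="fixed")
        b = repeated_cv(df, "y", ["score"], k=5, repeats=3, seed=9, selection="fixed")
        assert a.auroc_point == b.auroc_point
        np.testing.assert_array_equal(a.fold_aurocs, b.fold_aurocs)
        np.testing.assert_array_equal(a.oof_matrix, b.oof_matrix)

    def test_point_estimate_near_analytic(self):
        df = self._binormal_df(n=2000, seed=8)
        cv = repeated_cv(df, "y", ["score"], k=10, repeats=10, seed=1, selection="fixed")
        assert abs(cv.auroc_point - 0.80) < 0.03
        assert cv.auroc_ci_low <= cv.auroc_point <= cv.auroc_ci_high

    def test_too_few_events_raise(self):
        df = self._binormal_df(n=30)
        with pytest.raises(InputError):
            repeated_cv(df, "y", ["score"], k=25)

    def test_selection_never_sees_held_out_rows(self):
        # canary: outcome copied into a feature only on the test rows of one
        # designated fold; training rows carry pure noise there, so leak-free
        # CV must stay at the no-signal baseline
        rng = np.random.default_rng(10)
        n = 300
        y = (rng.uniform(size=n) < 0.5).astype(int)
        X = rng.standard_normal((n, 5))
        folds = stratified_fold_indices(y, k=10, repeats=1, seed=42)
        canary = rng.standard_normal(n)
        canary[folds[0][0]] = y[folds[0][0]].astype(float)
        df = pd.DataFrame(X, columns=[f"x{i}" for i in range(5)])
        df["canary"] = canary
        df["y"] = y
        cv = repeated_cv(df, "y", [f"x{i}" for i in range(5)] + ["canary"], k=10, repeats=1, seed=42)
        assert abs(cv.auroc_point - 0.5) <= 0.05


class TestModelSpecs:
    def test_combined_models_union_candidates(self):
        cols = ["age", "sex_male", "hr", "rr", "sbp", "dbp", "gcs", "marshall",
                "ecg_nn_sdnn_w15", "ppg_pp_sdnn_w15", "ecg_nn_sdnn_w60"]
        m2 = set(MODEL_SPECS[2].resolve(cols))
        m4 = set(MODEL_SPECS[4].resolve(cols))
        m5 = set(MODEL_SPECS[5].resolve(cols))
        assert set(MODEL_SPECS[8].resolve(cols)) == m2 | m4
        assert set(MODEL_SPECS[9].resolve(cols)) == m2 | m5
        assert "ecg_nn_sdnn_w60" in MODEL_SPECS[6].resolve(cols)
        assert "marshall" not in m2


class TestMortalityModel:
    def test_or_equals_cross_product_ratio_when_alone(self):
        y = np.array([1] * 20 + [0] * 10 + [1] * 10 + [0] * 20)
        x = np.array([1] * 30 + [0] * 30)
        fit = fit_logistic(pd.DataFrame({"x": x}), y)
        assert np.exp(fit.coefficients["x"]) == pytest.approx(4.0, abs=1e-4)

    def test_structure_and_recovery(self):
        rng = np.random.default_rng(11)
        n = 4000
        df = pd.DataFrame(
            {
                "age": rng.normal(45, 15, n),
                "marshall": rng.integers(1, 6, n).astype(float),
                "mechanism_penetrating": (rng.uniform(size=n) < 0.1).astype(int),
                "ppg15": rng.uniform(0.05, 0.6, n),
                "sex_male": (rng.uniform(size=n) < 0.7).astype(int),
                "map": rng.normal(100, 12, n),
                "hr": rng.normal(95, 14, n),
                "rr": rng.normal(19, 4, n),
                "gcs": rng.integers(3, 16, n).astype(float),
            }
        )
        lp = 0.0488 * (df["age"] - 45) + 1.18 * (df["ppg15"] - 0.3)  # OR 1.05/yr, 3.26/unit
        df["mortality"] = (rng.uniform(size=n) < expit(-2.0 + lp)).astype(int)
        table = mortality_model(df)
        age = table.set_index("covariate").loc["age"]
        assert age["ci_low"] <= 1.05 <= age["ci_high"]
        # a null covariate's CI should cover 1
        mech = table.set_index("covariate").loc["sex_male"]
        assert mech["ci_low"] <= 1.0 <= mech["ci_high"]

    def test_missing_required_covariate_raises(self):
        with pytest.raises(InputError):
            mortality_model(pd.DataFrame({"age": [1.0], "mortality": [1]}))


class TestPPG15:
    def test_null_distribution_near_prevalence(self):
        rng = np.random.default_rng(12)
        n = 400
        df = pd.DataFrame({"patient_id": [f"p{i}" for i in range(n)]})
        for j in range(4):
            df[f"ppg_f{j}_w15"] = rng.standard_normal(n)
        df["nd"] = (rng.uniform(size=n) < 0.25).astype(int)
        probs = ppg15_probability(df, seed=3, k=5, repeats=2)
        assert abs(probs.mean() - 0.25) < 0.06
        assert ((probs > 0) & (probs < 1)).all()

    def test_deterministic(self):
        rng = np.random.default_rng(13)
        df = pd.DataFrame({"patient_id": range(200)})
        df["ppg_a_w15"] = rng.standard_normal(200)
        df["nd"] = (rng.uniform(size=200) < 0.3).astype(int)
        p1 = ppg15_probability(df, seed=5, k=5, repeats=2)
        p2 = ppg15_probability(df, seed=5, k=5, repeats=2)
        np.testing.assert_array_equal(p1.to_numpy(), p2.to_numpy())
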