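"""Risk pipeline: troponin coding, screening, stepwise selection, LOOCV, ROC."""

import math

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from hrnv import (
    CohortSpec,
    encode_troponin,
    gen_cohort,
    loocv_probabilities,
    roc_analysis,
    stepwise_backward,
    univariable_screen,
)

from .oracles import pair_count_auc


class TestTroponinEncoding:
    @pytest.mark.parametrize("value,code", [
        (0.0, 0), (0.02, 0), (0.03, 0),        # at/below the normal limit
        (0.031, 1), (0.06, 1), (0.09, 1),       # 1-3x the limit (3x -> 1)
        (0.091, 2), (0.10, 2), (5.0, 2),        # above 3x
    ])
    def test_step_function(self, value, code):
        assert encode_troponin(value) == code

    def test_monotone_total_on_grid(self):
        codes = [encode_troponin(v) for v in np.linspace(0, 1, 2000)]
        assert all(b >= a for a, b in zip(codes, codes[1:]))

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            encode_troponin(-0.01)


class TestUnivariableScreen:
    def test_two_by_two_odds_ratio_from_counts(self):
        """Male sex 188/247 events vs 354/548: OR = (188*194)/(59*354) ~ 1.746."""
        male = [1] * 188 + [0] * 59 + [1] * 354 + [0] * 194
        outcome = [1] * 247 + [0] * 548
        df = pd.DataFrame({"male": male, "outcome": outcome})
        _, table = univariable_screen(df, ["male"])
        assert table.loc["male", "or_"] == pytest.approx(
            (188 * 194) / (59 * 354), rel=1e-3)

    def test_null_predictor_or_near_one(self, rng):
        df = pd.DataFrame({
            "x": rng.normal(0, 1, 4000),
            "outcome": rng.binomial(1, 0.3, 4000),
        })
        selected, table = univariable_screen(df, ["x"])
        assert table.loc["x", "or_"] == pytest.approx(1.0, abs=0.1)
        assert table.loc["x", "ci_lo"] < 1.0 < table.loc["x", "ci_hi"]

    def test_separation_flagged_and_excluded(self):
        y = np.array([0] * 50 + [1] * 50)
        df = pd.DataFrame({"x": y.astype(float), "outcome": y})
        with pytest.warns(UserWarning):
            selected, table = univariable_screen(df, ["x"])
        assert table.loc["x", "separation"]
        assert "x" not in selected

    def test_constant_candidate_rejected(self):
        df = pd.DataFrame({"x": [1.0] * 20, "outcome": [0, 1] * 10})
        with pytest.raises(ValueError):
            univariable_screen(df, ["x"])


class TestStepwise:
    def test_true_predictor_retained_nulls_dropped(self, rng):
        n = 5000
        x_true = rng.normal(0, 1, n)
        nulls = {f"z{i}": rng.normal(0, 1, n) for i in range(8)}
        logits = -1.0 + 1.2 * x_true
        y = rng.binomial(1, 1 / (1 + np.exp(-logits)))
        df = pd.DataFrame({"x_true": x_true, **nulls, "outcome": y})
        res = stepwise_backward(df, ["x_true", *nulls])
        assert "x_true" in res.variables
        assert all(res.table["p"] <= 0.05)
        assert all(res.table.loc[v, "ci_lo"] <= res.table.loc[v, "or_"]
                   <= res.table.loc[v, "ci_hi"] for v in res.variables)

    def test_all_null_false_retention_near_alpha(self, rng):
        """With pure-noise candidates the per-variable retention rate is on
        the order of the stopping alpha."""
        kept = 0
        trials, k = 30, 6
        for t in range(trials):
            r = np.random.default_rng(t)
            df = pd.DataFrame({f"z{i}": r.normal(0, 1, 400) for i in range(k)})
            df["outcome"] = r.binomial(1, 0.3, 400)
            kept += len(stepwise_backward(df, [f"z{i}" for i in range(k)]).variables)
        rate = kept / (trials * k)
        assert rate < 0.15

    def test_empty_candidates_gives_intercept_only(self, rng):
        df = pd.DataFrame({"outcome": rng.binomial(1, 0.4, 50)})
        res = stepwise_backward(df, [])
        assert res.variables == []

    def test_aic_criterion_runs(self, rng):
        n = 800
        x = rng.normal(0, 1, n)
        y = rng.binomial(1, 1 / (1 + np.exp(-(x - 0.5))))
        df = pd.DataFrame({"x": x, "z": rng.normal(0, 1, n), "outcome": y})
        res = stepwise_backward(df, ["x", "z"], criterion="aic")
        assert "x" in res.variables


class TestLOOCV:
    def test_small_cohort_folds_equal_manual_refits(self):
        # non-separable toy data so every fold has a finite MLE
        df = pd.DataFrame({
            "x": [0.1, 0.9, 0.4, 0.8, 0.2, 0.7],
            "outcome": [0, 1, 1, 0, 0, 1],
        })
        probs = loocv_probabilities(df, ["x"])
        for i in range(len(df)):
            rest = df.drop(index=i)
            fit = sm.Logit(rest["outcome"],
                           sm.add_constant(rest[["x"]])).fit(disp=0)
            manual = float(fit.predict([[1.0, df.loc[i, "x"]]])[0])
            assert probs[i] == pytest.approx(manual, abs=1e-6)

    def test_separable_data_near_perfect(self):
        df = pd.DataFrame({"x": np.r_[np.zeros(10), np.ones(10)] +
                           np.linspace(0, 0.1, 20),
                           "outcome": np.r_[np.zeros(10), np.ones(10)].astype(int)})
        probs = loocv_probabilities(df, ["x"])
        auc = roc_analysis(probs, df["outcome"].to_numpy()).auc
        assert auc > 0.95

    def test_shuffled_outcome_gives_chance_auc(self):
        df = gen_cohort(CohortSpec(n_patients=400, seed=6))
        r = np.random.default_rng(6)
        df["outcome"] = r.permutation(df["outcome"].to_numpy())
        probs = loocv_probabilities(df, ["age", "troponin_code", "hr2v_apen"])
        auc = roc_analysis(probs, df["outcome"].to_numpy()).auc
        assert 0.35 < auc < 0.6  # chance level minus LOOCV pessimism at n=400


class TestROC:
    def test_perfect_scores(self):
        y = np.array([0, 0, 1, 1, 1])
        res = roc_analysis(y.astype(float), y)
        assert res.auc == 1.0
        m = res.metrics_at_optimal
        assert m["sensitivity"] == 1.0 and m["specificity"] == 1.0

    def test_six_point_toy_auc(self):
        # one discordant pair (0.35 positive vs 0.4 negative) out of nine
        scores = [0.1, 0.2, 0.4, 0.35, 0.8, 0.7]
        y = [0, 0, 0, 1, 1, 1]
        assert pair_count_auc(scores, y) == pytest.approx(8 / 9, abs=1e-12)
        res = roc_analysis(scores, y)
        assert res.auc == pytest.approx(8 / 9, abs=1e-12)

    def test_trapezoid_equals_pair_counting(self, rng):
        """Empirical AUC equals the Mann-Whitney concordance on 200 random
        small data sets, including ties."""
        for _ in range(200):
            n = int(rng.integers(8, 40))
            scores = rng.integers(0, 10, n).astype(float)  # force ties
            y = rng.binomial(1, 0.5, n)
            if y.min() == y.max():
                continue
            res = roc_analysis(scores, y)
            assert res.auc == pytest.approx(pair_count_auc(scores, y), abs=1e-12)

    def test_random_scores_chance_auc(self, rng):
        scores = rng.uniform(0, 1, 5000)
        y = rng.binomial(1, 0.4, 5000)
        assert roc_analysis(scores, y).auc == pytest.approx(0.5, abs=0.03)

    def test_optimal_cutoff_minimises_corner_distance(self, rng):
        scores = rng.normal(0, 1, 300) + rng.binomial(1, 0.4, 300)
        y = (scores + rng.normal(0, 1, 300) > 0.7).astype(int)
        res = roc_analysis(scores, y)
        dist = np.hypot(1 - res.specificity, 1 - res.sensitivity)
        best = dist.min()
        m = res.metrics_at(res.optimal_cutoff)
        got = math.hypot(1 - m["specificity"], 1 - m["sensitivity"])
        assert got == pytest.approx(best, abs=1e-12)

    def test_delong_ci_brackets_auc(self, rng):
        scores = rng.normal(0, 1, 200)
        y = rng.binomial(1, 0.3, 200)
        res = roc_analysis(scores, y)
        assert res.auc_ci[0] <= res.auc <= res.auc_ci[1]

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            roc_analysis([0.1, 0.2], [1, 1])
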