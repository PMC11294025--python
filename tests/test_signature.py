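"""Transforms, selectors, CV occurrence aggregation, consensus and final fit."""

import numpy as np
import pandas as pd
import pytest

from peradiomics.signature import (
    ConsensusError,
    CVScheme,
    TransformParams,
    consensus_signature,
    fit_final,
    linear_parameters,
    run_cv,
    select_mim,
    select_mrmr,
    select_univariate,
    yeo_johnson,
)


class TestYeoJohnson:
    def test_lambda_one_is_identity(self):
        x = np.array([-3.0, -0.5, 0.0, 1.0, 7.5])
        np.testing.assert_allclose(yeo_johnson(x, 1.0), x, atol=1e-12)

    def test_lambda_zero_positive_branch(self):
        assert yeo_johnson(3.0, 0.0) == pytest.approx(np.log(4.0))

    def test_negative_branch_lambda_two(self):
        assert yeo_johnson(-0.5, 2.0) == pytest.approx(-np.log(1.5))

    def test_monotone_for_any_lambda(self):
        x = np.linspace(-5, 5, 101)
        for lam in (-1.0, 0.0, 0.5, 1.0, 2.0, 3.0):
            t = yeo_johnson(x, lam)
            assert np.all(np.diff(t) > 0), lam

    def test_transformer_z_scores_training_data(self):
        rng = np.random.default_rng(0)
        table = pd.DataFrame({"f": rng.lognormal(0, 1, 300)})
        tp = TransformParams().fit(table)
        t = tp.transform(table)
        assert t["f"].mean() == pytest.approx(0.0, abs=1e-9)
        assert t["f"].std() == pytest.approx(1.0, abs=0.01)
        # fitted transform reduces skewness of a lognormal sample
        raw_skew = table["f"].skew()
        assert abs(t["f"].skew()) < abs(raw_skew)


def _selection_problem(n=200, seed=0):
    rng = np.random.default_rng(seed)
    y = (rng.random(n) < 0.35).astype(int)
    table = pd.DataFrame({
        "signal": y * 1.8 + rng.normal(0, 1, n),
        "copy": None,
        "weak": y * 0.8 + rng.normal(0, 1, n),
        "noise1": rng.normal(0, 1, n),
        "noise2": rng.normal(0, 1, n),
    })
    table["copy"] = table["signal"] + rng.normal(0, 0.05, n)
    return table, y


class TestSelectors:
    def test_informative_feature_ranked_first_everywhere(self):
        table, y = _selection_problem()
        for select in (select_mim, select_mrmr, select_univariate):
            assert select(table, y, 3)[0] in ("signal", "copy")

    def test_mrmr_defers_duplicate_behind_independent_feature(self):
        table, y = _selection_problem()
        picks = select_mrmr(table, y, 3)
        first = picks[0]
        dup = "copy" if first == "signal" else "signal"
        assert picks[1] != dup  # the near-duplicate is penalized
        assert dup not in picks[:2]

    def test_mrmr_k1_equals_mim_top_choice(self):
        table, y = _selection_problem(seed=3)
        assert select_mrmr(table, y, 1) == select_mim(table, y, 1)

    def test_k_larger_than_feature_count_returns_all(self):
        table, y = _selection_problem()
        assert len(select_mim(table, y, 50)) == table.shape[1]
        assert len(select_univariate(table, y, 50)) == table.shape[1]

    def test_univariate_survives_complete_separation(self):
        rng = np.random.default_rng(1)
        n = 60
        y = np.array([0] * 30 + [1] * 30)
        table = pd.DataFrame({
            "separator": np.concatenate([rng.normal(-3, 0.1, 30),
                                         rng.normal(3, 0.1, 30)]),
            "noise": rng.normal(0, 1, n),
        })
        picks = select_univariate(table, y, 2)
        assert picks[0] == "separator"


class TestRunCV:
    def test_deterministic_and_dominant_feature_always_selected(self):
        table, y = _selection_problem(n=120, seed=5)
        scheme = CVScheme(folds=3, repeats=2, seed=9)
        res1 = run_cv(table, y, scheme, learners=("glm_logistic",), tune_draws=2)
        res2 = run_cv(table, y, scheme, learners=("glm_logistic",), tune_draws=2)
        pd.testing.assert_frame_equal(res1.occurrence, res2.occurrence)
        pd.testing.assert_frame_equal(res1.run_aucs, res2.run_aucs)
        top = res1.occurrence.max(axis=1)
        assert top[["signal", "copy"]].max() == 100.0

    def test_permuted_labels_give_chance_auc(self):
        table, y = _selection_problem(n=150, seed=6)
        rng = np.random.default_rng(0)
        y_perm = rng.permutation(y)
        res = run_cv(table, y_perm, CVScheme(folds=3, repeats=2, seed=1),
                     learners=("glm_logistic",), tune_draws=2)
        med = res.run_aucs["auc"].median()
        assert 0.4 <= med <= 0.6

    def test_too_few_events_rejected(self):
        table, _ = _selection_problem(n=30)
        y = np.zeros(30, int)
        y[0] = 1
        with pytest.raises(ValueError, match="events"):
            run_cv(table, y, CVScheme())


class TestConsensus:
    def _occ(self, data):
        return pd.DataFrame(data).fillna(0.0)

    def test_worked_example_single_survivor(self):
        occ = self._occ({
            "mrmr": {"f1": 80.0, "f2": 60.0, "f3": 0.0},
            "mim": {"f1": 70.0, "f2": 0.0, "f3": 55.0},
            "univariate": {"f1": 0.0, "f2": 0.0, "f3": 40.0},
        })
        table = pd.DataFrame(np.random.default_rng(0).normal(0, 1, (30, 3)),
                             columns=["f1", "f2", "f3"])
        assert consensus_signature(occ, table) == ["f1"]

    def test_correlated_pair_pruned_by_occurrence(self):
        occ = self._occ({
            "mrmr": {"f1": 80.0, "f2": 60.0},
            "mim": {"f1": 70.0, "f2": 60.0},
            "univariate": {"f1": 75.0, "f2": 60.0},
        })
        rng = np.random.default_rng(1)
        f1 = rng.normal(0, 1, 40)
        table = pd.DataFrame({"f1": f1, "f2": f1 + rng.normal(0, 0.1, 40)})
        assert consensus_signature(occ, table) == ["f1"]

    def test_all_below_threshold_is_error(self):
        occ = self._occ({
            "mrmr": {"f1": 40.0}, "mim": {"f1": 50.0}, "univariate": {"f1": 20.0},
        })
        table = pd.DataFrame({"f1": np.arange(30.0)})
        with pytest.raises(ConsensusError, match="threshold"):
            consensus_signature(occ, table)


class TestFinalFit:
    def test_separable_toy_data_perfect_training_auc(self):
        rng = np.random.default_rng(2)
        n = 80
        y = np.array([0] * 40 + [1] * 40)
        table = pd.DataFrame({
            "f1": np.concatenate([rng.normal(-2, 0.3, 40), rng.normal(2, 0.3, 40)]),
            "f2": rng.normal(0, 1, n),
        })
        fit = fit_final(table, y, ["f1", "f2"], "xgb_lm", seed=0, tune_draws=4)
        from peradiomics.evaluation import roc_auc

        assert roc_auc(fit.predict(table).to_numpy(), y) == 1.0

    def test_boosted_linear_model_reduces_to_linear_score(self):
        table, y = _selection_problem(n=150, seed=8)
        fit = fit_final(table, y, ["signal", "weak"], "xgb_lm", seed=1, tune_draws=4)
        probs = fit.predict(table).to_numpy()
        lin = fit.linear_score(table).to_numpy()
        np.testing.assert_allclose(probs, 1.0 / (1.0 + np.exp(-lin)), atol=1e-5)
        coef, intercept = linear_parameters(fit.model)
        assert coef.shape == (2,)

    def test_parameter_recovery_on_generative_model(self):
        # logit(p) = -2 + 1.0 * x1 - 0.7 * x2, n = 2000
        rng = np.random.default_rng(3)
        n = 2000
        x1 = rng.normal(0, 1, n)
        x2 = rng.normal(0, 1, n)
        p = 1.0 / (1.0 + np.exp(-(-2.0 + 1.0 * x1 - 0.7 * x2)))
        y = (rng.random(n) < p).astype(int)
        table = pd.DataFrame({"x1": x1, "x2": x2})
        fit = fit_final(table, y, ["x1", "x2"], "glm_logistic", seed=0)
        coef, _ = linear_parameters(fit.model)
        # features are z-scored (unit variance) so coefficients compare directly
        assert coef[0] == pytest.approx(1.0, rel=0.25)
        assert coef[1] == pytest.approx(-0.7, rel=0.25)

    def test_predict_contracts(self):
        table, y = _selection_problem(n=100, seed=9)
        fit = fit_final(table, y, ["signal"], "glm_logistic", seed=0)
        p1 = fit.predict(table)
        shuffled = table.sample(frac=1.0, random_state=0)
        p2 = fit.predict(shuffled)
        pd.testing.assert_series_equal(p1.loc[shuffled.index], p2)
        broken = table.copy()
        broken.iloc[3, broken.columns.get_loc("signal")] = np.nan
        with pytest.raises(ValueError, match="signal"):
            fit.predict(broken)
        with pytest.raises(ValueError, match="missing signature features"):
            fit.predict(table.drop(columns=["signal"]))
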