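"""ROC/AUC, bootstrap CI, DeLong comparison, Youden cut-off, calibration."""

import numpy as np
import pytest
from scipy import stats

from oracles import bf_auc, bf_delong_variance
from peradiomics.evaluation import (
    auc_ci_bootstrap,
    confusion_at,
    delong_test,
    hosmer_lemeshow,
    roc_auc,
    wald_importance,
    youden_cutoff,
)


class TestAUC:
    def test_perfect_ranking(self):
        assert roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_all_ties_half(self):
        assert roc_auc([0.5] * 6, [0, 1, 0, 1, 0, 1]) == 0.5

    def test_toy_set_matches_pair_counting(self):
        scores = [0.2, 0.5, 0.5, 0.7, 0.3, 0.9]
        labels = [0, 1, 0, 1, 0, 1]
        assert roc_auc(scores, labels) == pytest.approx(bf_auc(scores, labels))

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(0, 1, 100)
        labels = (rng.random(100) < 0.4).astype(int)
        a = roc_auc(scores, labels)
        b = roc_auc(np.exp(scores * 3.0), labels)
        assert a == pytest.approx(b)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])


class TestBootstrapCI:
    def test_perfect_classifier_degenerate_interval(self):
        scores = np.concatenate([np.zeros(20), np.ones(20)])
        labels = scores.astype(int)
        lo, hi = auc_ci_bootstrap(scores, labels, b=200, seed=0)
        assert lo == hi == 1.0

    def test_reproducible_given_seed(self):
        rng = np.random.default_rng(1)
        scores = rng.normal(0, 1, 80)
        labels = (rng.random(80) < 0.4).astype(int)
        assert auc_ci_bootstrap(scores, labels, b=200, seed=5) == \
            auc_ci_bootstrap(scores, labels, b=200, seed=5)

    def test_interval_brackets_point_estimate(self):
        rng = np.random.default_rng(2)
        labels = (rng.random(120) < 0.3).astype(int)
        scores = labels * 1.0 + rng.normal(0, 1, 120)
        lo, hi = auc_ci_bootstrap(scores, labels, b=500, seed=0)
        assert lo < roc_auc(scores, labels) < hi


class TestDeLong:
    def test_identical_scores_no_difference(self):
        rng = np.random.default_rng(0)
        s = rng.normal(0, 1, 60)
        y = (rng.random(60) < 0.5).astype(int)
        diff, z, p = delong_test(s, s, y)
        assert diff == 0.0 and p == 1.0

    def test_variance_matches_structural_components(self):
        rng = np.random.default_rng(1)
        y = np.array([1] * 8 + [0] * 12)
        a = rng.normal(0.5, 1, 20) + y
        # compare A against a totally uninformative constant marker:
        # the paired variance then reduces to the single-marker variance
        b = np.zeros(20)
        _, auc_var = bf_delong_variance(a[y == 1], a[y == 0])
        diff, z, p = delong_test(a, b, y)
        want_z = (roc_auc(a, y) - 0.5) / np.sqrt(auc_var)
        assert z == pytest.approx(want_z)

    def test_null_type_one_error_calibrated(self):
        # independent useless markers: rejection rate ~ alpha
        rng = np.random.default_rng(2)
        n, sims, alpha = 300, 400, 0.05
        rejections = 0
        for _ in range(sims):
            y = np.concatenate([np.ones(60, int), np.zeros(240, int)])
            a = rng.normal(0, 1, n)
            b = rng.normal(0, 1, n)
            _, _, p = delong_test(a, b, y)
            rejections += p < alpha
        assert 0.02 <= rejections / sims <= 0.08


class TestYouden:
    def test_separable_returns_gap_midpoint(self):
        scores = [0.1, 0.2, 0.3, 0.7, 0.8, 0.9]
        labels = [0, 0, 0, 1, 1, 1]
        cut = youden_cutoff(scores, labels)
        assert cut == pytest.approx(0.5)
        conf = confusion_at(scores, labels, cut)
        assert conf["tp"] == 3 and conf["tn"] == 3

    def test_matches_exhaustive_threshold_scan(self):
        scores = np.array([0.1, 0.4, 0.35, 0.8, 0.65, 0.9, 0.5, 0.2])
        labels = np.array([0, 0, 1, 1, 0, 1, 1, 0])
        cut = youden_cutoff(scores, labels)
        best_j = -np.inf
        for thr in np.unique(scores):
            pred = scores >= thr
            j = (pred & (labels == 1)).sum() / 4 + (~pred & (labels == 0)).sum() / 4 - 1
            best_j = max(best_j, j)
        conf = confusion_at(scores, labels, cut)
        got_j = conf["tp"] / 4 + conf["tn"] / 4 - 1
        assert got_j == pytest.approx(best_j)

    def test_training_cutoff_self_consistency(self):
        rng = np.random.default_rng(3)
        labels = (rng.random(200) < 0.3).astype(int)
        scores = labels + rng.normal(0, 1, 200)
        cut = youden_cutoff(scores, labels)
        conf = confusion_at(scores, labels, cut)
        sens = conf["tp"] / (conf["tp"] + conf["fn"])
        spec = conf["tn"] / (conf["tn"] + conf["fp"])
        assert conf["tp"] + conf["fp"] + conf["fn"] + conf["tn"] == 200
        assert 0 <= sens <= 1 and 0 <= spec <= 1


class TestHosmerLemeshow:
    def test_two_group_table_direct_formula(self):
        probs = np.array([0.2] * 10 + [0.8] * 10)
        labels = np.array([0] * 8 + [1] * 2 + [1] * 7 + [0] * 3)
        chi2, p, g = hosmer_lemeshow(probs, labels, g=2)
        exp1, exp2 = 2.0, 8.0
        want = ((2 - exp1) ** 2 / exp1 + (8 - 8.0) ** 2 / 8.0
                + (7 - exp2) ** 2 / exp2 + (3 - 2.0) ** 2 / 2.0)
        assert chi2 == pytest.approx(want)

    def test_constant_prevalence_prediction_near_zero_chi2(self):
        rng = np.random.default_rng(4)
        labels = (rng.random(400) < 0.3).astype(int)
        probs = np.full(400, labels.mean())
        chi2, p, _ = hosmer_lemeshow(probs, labels)
        assert chi2 == pytest.approx(0.0, abs=1e-9)

    def test_well_calibrated_probs_not_rejected(self):
        rng = np.random.default_rng(5)
        probs = rng.uniform(0.05, 0.95, 500)
        labels = (rng.random(500) < probs).astype(int)
        _, p, _ = hosmer_lemeshow(probs, labels)
        assert p > 0.01


class TestWaldImportance:
    def test_strong_effect_significant(self):
        import pandas as pd

        rng = np.random.default_rng(6)
        n = 300
        y = (rng.random(n) < 0.35).astype(int)
        table = pd.DataFrame({
            "strong": y * 2.0 + rng.normal(0, 1, n),
            "null": rng.normal(0, 1, n),
        })
        p = wald_importance(table, y, ["strong", "null"])
        assert p["strong"] < 0.01
        assert p["null"] > 0.01

    def test_affine_invariance(self):
        import pandas as pd

        rng = np.random.default_rng(7)
        n = 200
        y = (rng.random(n) < 0.4).astype(int)
        x = y + rng.normal(0, 1, n)
        t1 = pd.DataFrame({"f": x})
        t2 = pd.DataFrame({"f": 100.0 * x - 40.0})
        p1 = wald_importance(t1, y, ["f"])["f"]
        p2 = wald_importance(t2, y, ["f"])["f"]
        assert p1 == pytest.approx(p2, rel=1e-4)


class TestPlotExports:
    def test_roc_points_span_the_unit_square(self):
        from peradiomics.evaluation import roc_points

        rng = np.random.default_rng(8)
        labels = (rng.random(100) < 0.3).astype(int)
        scores = labels + rng.normal(0, 1, 100)
        pts = roc_points(scores, labels)
        assert pts["sensitivity"].iloc[-1] == 1.0
        assert pts["fpr"].iloc[-1] == 1.0
        assert pts["sensitivity"].is_monotonic_increasing
        assert pts["fpr"].is_monotonic_increasing

    def test_calibration_points_recover_group_rates(self):
        from peradiomics.evaluation import calibration_points

        probs = np.array([0.1] * 50 + [0.9] * 50)
        labels = np.array([0] * 45 + [1] * 5 + [1] * 45 + [0] * 5)
        pts = calibration_points(probs, labels, g=2)
        assert len(pts) == 2
        np.testing.assert_allclose(pts["observed_rate"], [0.1, 0.9])
        assert pts["n"].sum() == 100
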