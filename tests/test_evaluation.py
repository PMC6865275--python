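"""Evaluation statistics: metrics, bootstrap CIs, McNemar-Bowker, ROC."""

import numpy as np
import pytest
from scipy import stats as sps

from gridattn.classes import CLASS_ORDER, NORMAL
from gridattn.evaluation import (
    bootstrap_ci,
    confusion_matrix,
    mcnemar_bowker,
    mean_metrics,
    metrics_report,
    one_vs_rest_metrics,
    roc_auc_one_vs_rest,
)

class TestOneVsRest:
    def test_perfect_diagonal_gives_all_ones(self):
        cm = np.diag([10, 5, 3, 7])
        for cls in CLASS_ORDER:
            m = one_vs_rest_metrics(cm, cls)
            for name in ("accuracy", "recall", "precision", "specificity", "f1"):
                assert m[name] == 1.0

    def test_hand_computed_toy_counts(self):
        # TP=3, FP=1, FN=2, TN=4 for class 0
        cm = np.array([[3, 2], [1, 4]])
        m = one_vs_rest_metrics(cm, 0, classes=("pos", "neg"))
        assert m["recall"] == pytest.approx(0.6, abs=1e-12)
        assert m["precision"] == pytest.approx(0.75, abs=1e-12)
        assert m["accuracy"] == pytest.approx(0.7, abs=1e-12)
        assert m["specificity"] == pytest.approx(0.8, abs=1e-12)
        assert m["f1"] == pytest.approx(2 * 0.75 * 0.6 / 1.35, abs=1e-12)

    def test_absent_class_flagged_undefined(self):
        cm = np.zeros((4, 4), int)
        cm[0, 0] = 10  # only normals present and predicted
        m = one_vs_rest_metrics(cm, CLASS_ORDER[3])
        assert m["recall"] == 0.0
        assert "recall" in m["undefined"]

    def test_invalid_matrix_rejected(self):
        with pytest.raises(ValueError):
            one_vs_rest_metrics(np.zeros((4, 4), int), NORMAL)


class TestMeanMetrics:
    def test_identical_classes_mean_is_that_value(self):
        per = {c: dict(accuracy=0.9, recall=0.9, precision=0.9,
                       specificity=0.9, f1=0.9) for c in CLASS_ORDER}
        assert mean_metrics(per)["accuracy"] == pytest.approx(0.9)

    def test_reported_per_class_accuracies_average_to_083(self):
        """The four one-vs-rest accuracies 0.70/0.85/0.89/0.88 have an
        unweighted mean of 0.83 — the headline mean-accuracy convention."""
        vals = (0.70, 0.85, 0.89, 0.88)
        per = {c: dict(accuracy=v, recall=0, precision=0, specificity=0, f1=0)
               for c, v in zip(CLASS_ORDER, vals)}
        assert mean_metrics(per)["accuracy"] == pytest.approx(0.83, abs=0.0051)

    def test_simple_mean(self):
        per = {c: dict(accuracy=v, recall=v, precision=v, specificity=v, f1=v)
               for c, v in zip(CLASS_ORDER, (0, 1, 1, 1))}
        assert mean_metrics(per)["f1"] == pytest.approx(0.75)


def _accuracy(y, p):
    return float((np.asarray(y) == np.asarray(p)).mean())


class TestBootstrap:
    def test_perfect_predictions_give_degenerate_interval(self):
        y = np.array([NORMAL] * 20)
        pt, lo, hi = bootstrap_ci(y, y, _accuracy, B=200, seed=0)
        assert (pt, lo, hi) == (1.0, 1.0, 1.0)

    def test_point_estimate_is_plug_in_value(self, rng):
        y = rng.choice(CLASS_ORDER, size=50)
        p = rng.choice(CLASS_ORDER, size=50)
        pt, lo, hi = bootstrap_ci(y, p, _accuracy, B=300, seed=1)
        assert pt == _accuracy(y, p)
        assert lo <= pt <= hi

    def test_seed_determinism(self, rng):
        y = rng.choice(CLASS_ORDER, size=40)
        p = rng.choice(CLASS_ORDER, size=40)
        assert bootstrap_ci(y, p, _accuracy, B=300, seed=7) == \
            bootstrap_ci(y, p, _accuracy, B=300, seed=7)

    def test_interval_narrows_with_sample_size(self):
        """CI width at n=1000 is smaller than at n=100 for the same
        generating process (accuracy 0.8)."""
        rng = np.random.default_rng(0)

        def width(n):
            y = np.array([NORMAL] * n)
            p = np.where(rng.random(n) < 0.8, NORMAL, CLASS_ORDER[1])
            _, lo, hi = bootstrap_ci(y, p, _accuracy, B=400, seed=2)
            return hi - lo

        assert width(1000) < width(100)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_ci([NORMAL], [NORMAL], _accuracy)


class TestMcNemarBowker:
    def test_symmetric_disagreement_gives_zero_statistic(self):
        a = [NORMAL, CLASS_ORDER[1], NORMAL, CLASS_ORDER[1]]
        b = [CLASS_ORDER[1], NORMAL, CLASS_ORDER[1], NORMAL]
        stat, df, p = mcnemar_bowker(a, b)
        assert stat == 0.0
        assert p == 1.0

    def test_two_class_closed_form(self):
        """n_01=6, n_10=2: statistic (6-2)^2/8 = 2.0, p = P(chi2_1 > 2)."""
        a = [NORMAL] * 6 + [CLASS_ORDER[1]] * 2 + [NORMAL] * 5
        b = [CLASS_ORDER[1]] * 6 + [NORMAL] * 2 + [NORMAL] * 5
        stat, df, p = mcnemar_bowker(a, b)
        assert stat == pytest.approx(2.0)
        assert df == 1
        assert p == pytest.approx(sps.chi2.sf(2.0, 1), abs=1e-6)
        assert p == pytest.approx(0.1573, abs=5e-4)

    def test_invariant_to_category_relabeling(self, rng):
        a = rng.choice(CLASS_ORDER, size=60)
        b = rng.choice(CLASS_ORDER, size=60)
        stat1, df1, p1 = mcnemar_bowker(a, b)
        perm = list(reversed(CLASS_ORDER))
        remap = dict(zip(CLASS_ORDER, perm))
        stat2, df2, p2 = mcnemar_bowker([remap[x] for x in a], [remap[x] for x in b])
        assert stat1 == pytest.approx(stat2)
        assert df1 == df2

    def test_agrees_with_statsmodels_on_dense_table(self, rng):
        """Cross-check against the independent statsmodels implementation
        on a table with every off-diagonal pair populated."""
        statsmodels = pytest.importorskip("statsmodels.stats.contingency_tables")
        a = rng.choice(CLASS_ORDER, size=400)
        b = rng.choice(CLASS_ORDER, size=400)
        stat, df, p = mcnemar_bowker(a, b)
        table = confusion_matrix(a, b)
        assert df == 6  # dense table: the df conventions coincide
        res = statsmodels.SquareTable(table).symmetry()
        assert stat == pytest.approx(res.statistic, rel=1e-9)
        assert p == pytest.approx(res.pvalue, rel=1e-6)


class TestRocAuc:
    def _probs(self, scores, idx=1):
        p = np.zeros((len(scores), 4))
        p[:, idx] = scores
        p[:, 0] = 1 - np.asarray(scores)
        return p

    def test_perfect_separation_auc_one(self):
        labels = np.array([CLASS_ORDER[1]] * 2 + [NORMAL] * 2)
        _, _, auc = roc_auc_one_vs_rest(labels, self._probs([0.9, 0.8, 0.4, 0.3]),
                                        CLASS_ORDER[1])
        assert auc == 1.0

    def test_random_scores_give_half(self):
        rng = np.random.default_rng(3)
        n = 4000
        labels = np.where(rng.random(n) < 0.5, NORMAL, CLASS_ORDER[1])
        _, _, auc = roc_auc_one_vs_rest(labels, self._probs(rng.random(n)),
                                        CLASS_ORDER[1])
        assert auc == pytest.approx(0.5, abs=0.05)

    def test_single_class_flagged_undefined(self):
        labels = np.array([NORMAL] * 4)
        with pytest.warns(UserWarning, match="undefined"):
            _, _, auc = roc_auc_one_vs_rest(labels, self._probs([0.1, 0.2, 0.3, 0.4]),
                                            CLASS_ORDER[1])
        assert np.isnan(auc)


class TestMetricsReport:
    def test_report_structure_and_bounds(self, rng):
        y = rng.choice(CLASS_ORDER, size=80)
        p = np.where(rng.random(80) < 0.7, y, rng.choice(CLASS_ORDER, size=80))
        report = metrics_report(y, p, B=200, seed=0)
        t = report.table
        assert set(t["class"]) == set(CLASS_ORDER) | {"mean"}
        assert ((t.ci_low <= t.point + 1e-12) & (t.point <= t.ci_high + 1e-12)).all()
        assert ((t.point >= 0) & (t.point <= 1)).all()

    def test_confusion_total_preserved(self, rng):
        y = rng.choice(CLASS_ORDER, size=50)
        p = rng.choice(CLASS_ORDER, size=50)
        cm = confusion_matrix(y, p)
        assert cm.sum() == 50
        # one-vs-rest collapse preserves the total for every class
        for cls in CLASS_ORDER:
            m = one_vs_rest_metrics(cm, cls)
            assert cm.sum() == 50
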