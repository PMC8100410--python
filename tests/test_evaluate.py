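"""Confusion-matrix metrics and one-vs-rest ROC/AUC."""

import numpy as np
import pytest

from adseverity.evaluate import (ConfusionMatrix, accuracy, confusion,
                                 evaluation_report, macro_auc, precision,
                                 roc_one_vs_rest, sensitivity)


def _brute_force_auc(scores, positive):
    """Mann-Whitney concordance: P(score_pos > score_neg) + 0.5 P(tie)."""
    pos = scores[positive]
    neg = scores[~positive]
    wins = ties = 0
    for p in pos:
        for n in neg:
            wins += p > n
            ties += p == n
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


class TestConfusion:
    def test_perfect_predictions_diagonal(self):
        t = np.array([0, 1, 2, 3, 3])
        cm = confusion(t, t)
        assert np.all(cm.counts == np.diag([1, 1, 1, 2]))

    def test_single_predicted_column(self):
        cm = confusion([0, 1, 2, 3], [0, 0, 0, 0])
        assert np.all(cm.counts[:, 1:] == 0)
        assert np.all(cm.counts[:, 0] == 1)

    def test_published_low_severity_row(self):
        """656 of 690 low-severity patients correct, 30 as mild, 4 as moderate."""
        true = np.zeros(690, dtype=int)
        pred = np.concatenate([np.zeros(656), np.ones(30), np.full(4, 2)]).astype(int)
        cm = confusion(true, pred)
        np.testing.assert_array_equal(cm.counts[0], [656, 30, 4, 0])

    def test_relabelling_equivariance(self, rng):
        t = rng.integers(0, 4, 100)
        p = rng.integers(0, 4, 100)
        perm = np.array([2, 0, 3, 1])
        cm = confusion(t, p)
        cm2 = confusion(perm[t], perm[p])
        np.testing.assert_array_equal(cm2.counts[np.ix_(perm, perm)], cm.counts)

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            confusion([0, 4], [0, 0])


class TestPerClassMetrics:
    def test_published_sensitivity_value(self):
        counts = np.zeros((4, 4), dtype=int)
        counts[0] = [656, 30, 4, 0]
        counts[1, 1] = counts[2, 2] = counts[3, 3] = 1
        sens = sensitivity(ConfusionMatrix(counts))
        assert round(100 * sens[0], 1) == 95.1

    def test_diagonal_matrix_all_perfect(self):
        cm = ConfusionMatrix(np.diag([5, 3, 2, 1]))
        np.testing.assert_allclose(sensitivity(cm), 1.0)
        np.testing.assert_allclose(precision(cm), 1.0)
        assert accuracy(cm) == 1.0

    def test_empty_class_is_nan_not_zero(self):
        counts = np.diag([5, 3, 2, 0])
        sens = sensitivity(ConfusionMatrix(counts))
        assert np.isnan(sens[3]) and not np.isnan(sens[0])
        prec = precision(ConfusionMatrix(counts))
        assert np.isnan(prec[3])

    def test_two_class_toy(self):
        counts = np.zeros((4, 4), dtype=int)
        counts[:2, :2] = [[8, 2], [2, 8]]
        cm = ConfusionMatrix(counts)
        np.testing.assert_allclose(precision(cm)[:2], [0.8, 0.8])
        assert accuracy(cm) == pytest.approx(0.8)

    def test_accuracy_is_sensitivity_weighted_mean(self, rng):
        t = rng.integers(0, 4, 300)
        p = rng.integers(0, 4, 300)
        cm = confusion(t, p)
        sens = sensitivity(cm)
        weights = cm.counts.sum(axis=1) / cm.total
        assert accuracy(cm) == pytest.approx(np.nansum(sens * weights), abs=1e-12)

    def test_all_off_diagonal_zero_accuracy(self):
        cm = confusion([0, 1], [1, 0])
        assert accuracy(cm) == 0.0


class TestRoc:
    def test_perfect_ranking_auc_one(self):
        t = np.array([0, 0, 1, 1])
        scores = np.array([0.9, 0.8, 0.1, 0.2])
        assert roc_one_vs_rest(scores, t, 0).auc == pytest.approx(1.0)

    def test_constant_scores_auc_half(self):
        t = np.array([0, 0, 1, 1, 2])
        curve = roc_one_vs_rest(np.full(5, 0.5), t, 0)
        assert curve.auc == pytest.approx(0.5)

    def test_curve_monotone(self, rng):
        t = rng.integers(0, 4, 80)
        s = rng.uniform(size=80)
        curve = roc_one_vs_rest(s, t, 1)
        assert np.all(np.diff(curve.fpr) >= 0)
        assert np.all(np.diff(curve.tpr) >= 0)

    def test_auc_equals_brute_force_concordance(self, rng):
        for _ in range(5):
            n = int(rng.integers(20, 200))
            t = rng.integers(0, 4, n)
            if not np.any(t == 2):
                continue
            s = np.round(rng.uniform(size=n), 2)  # rounding forces ties
            auc = roc_one_vs_rest(s, t, 2).auc
            assert auc == pytest.approx(_brute_force_auc(s, t == 2), abs=1e-12)

    def test_random_scores_null_auc(self):
        aucs = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            t = rng.integers(0, 2, 1000)
            aucs.append(roc_one_vs_rest(rng.uniform(size=1000), t, 1).auc)
        assert 0.45 < np.mean(aucs) < 0.55

    def test_absent_positive_class_rejected(self):
        with pytest.raises(ValueError):
            roc_one_vs_rest(np.ones(3), np.zeros(3, dtype=int), 2)


def test_evaluation_report_layout(rng):
    t = rng.integers(0, 4, 120)
    p = t.copy()
    flip = rng.choice(120, 20, replace=False)
    p[flip] = rng.integers(0, 4, 20)
    scores = np.zeros((120, 4))
    scores[np.arange(120), p] = 1.0
    rep = evaluation_report(t, p, scores)
    assert rep["class_order"] == ["low", "mild", "moderate", "severe"]
    assert np.array(rep["confusion_matrix"]).sum() == 120
    assert isinstance(rep["accuracy_pct"], float)
    assert len(rep["sensitivity_pct"]) == 4 and len(rep["auc"]) == 4
    assert 0 <= rep["macro_auc"] <= 1
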