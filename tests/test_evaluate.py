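"""Confusion-matrix metrics, BCE, AUC: closed forms and library cross-checks."""

import math

import numpy as np
import pytest
from sklearn.metrics import precision_score, recall_score, roc_auc_score, roc_curve

import glaucopt as g
from glaucopt.evaluate import ConfusionCounts, evaluate_scores, f1_from


class TestBCE:
    def test_confident_correct_is_near_zero(self):
        assert g.bce_loss([1.0], [1.0]) == pytest.approx(0.0, abs=1e-6)

    def test_half_probability_is_ln2(self):
        assert g.bce_loss([1.0], [0.5]) == pytest.approx(math.log(2), rel=1e-12)

    def test_batch_mean(self):
        assert g.bce_loss([1, 0], [0.5, 0.5]) == pytest.approx(math.log(2), rel=1e-12)

    def test_clipping_keeps_saturated_outputs_finite(self):
        assert np.isfinite(g.bce_loss([1.0], [0.0]))
        assert g.bce_loss([1.0], [0.0]) == pytest.approx(-math.log(1e-7), rel=1e-9)


class TestConfusion:
    def test_perfect_scores_have_no_errors(self):
        c = g.confusion([1, 1, 0, 0], [0.9, 0.8, 0.1, 0.2], positive_class=1)
        assert (c.FP, c.FN) == (0, 0)

    def test_constructed_counts(self):
        labels = [1, 1, 1, 1, 1, 0, 0, 0, 0, 0]
        preds = [0.9, 0.8, 0.7, 0.2, 0.1, 0.6, 0.4, 0.3, 0.2, 0.1]
        c = g.confusion(labels, preds, positive_class=1)
        assert (c.TP, c.FN, c.FP, c.TN) == (3, 2, 1, 4)
        assert c.n == 10

    def test_threshold_ties_classified_positive(self):
        c = g.confusion([1, 0], [0.5, 0.5], positive_class=1)
        assert (c.TP, c.FP) == (1, 1)

    def test_string_labels_and_orientation(self):
        labels = ["glaucoma", "normal", "normal"]
        scores = [0.9, 0.2, 0.4]
        pos = g.confusion(labels, scores, positive_class="glaucoma")
        neg = g.confusion(labels, scores, positive_class="normal")
        assert (pos.TP, pos.TN) == (1, 2)
        assert (neg.TP, neg.TN) == (2, 1)

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="unknown class"):
            g.confusion(["glaucoma", "maybe"], [0.5, 0.5])


class TestMetrics:
    def test_direct_arithmetic(self):
        m = g.metrics(ConfusionCounts(TP=3, TN=4, FP=1, FN=2))
        assert m.prec == pytest.approx(0.75)
        assert m.sen == pytest.approx(0.6)
        assert m.f1 == pytest.approx(2 * 0.75 * 0.6 / 1.35, rel=1e-12)
        assert m.acc == pytest.approx(0.7)
        assert m.undefined == ()

    def test_all_correct_is_all_ones(self):
        m = g.metrics(ConfusionCounts(TP=5, TN=5, FP=0, FN=0))
        assert (m.acc, m.prec, m.sen, m.f1) == (1.0, 1.0, 1.0, 1.0)

    def test_published_normal_row_f1(self):
        """PREC 93.10 and SEN 92.31 (the ensemble's test-set normal row)
        combine to F1 92.70."""
        assert 100 * f1_from(0.9310, 0.9231) == pytest.approx(92.70, abs=0.01)

    def test_zero_denominator_flagged_not_zeroed(self):
        m = g.metrics(ConfusionCounts(TP=0, TN=5, FP=0, FN=0))
        assert math.isnan(m.prec) and "prec" in m.undefined
        assert math.isnan(m.f1) and "f1" in m.undefined

    def test_f1_between_prec_and_sen(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            tp, tn, fp, fn = rng.integers(1, 30, size=4)
            m = g.metrics(ConfusionCounts(int(tp), int(tn), int(fp), int(fn)))
            assert min(m.prec, m.sen) - 1e-12 <= m.f1 <= max(m.prec, m.sen) + 1e-12

    def test_agrees_with_sklearn_recount(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            y = rng.integers(0, 2, 40)
            s = rng.random(40)
            if y.sum() in (0, 40):
                continue
            pred = (s >= 0.5).astype(int)
            c = g.confusion(y, s, positive_class=1)
            m = g.metrics(c)
            assert m.prec == pytest.approx(precision_score(y, pred, zero_division=np.nan), nan_ok=True)
            assert m.sen == pytest.approx(recall_score(y, pred))


class TestAUC:
    def test_perfect_separation(self):
        assert g.auc([1, 1, 0, 0], [0.9, 0.8, 0.2, 0.1], positive_class=1) == 1.0

    def test_all_ties_half(self):
        assert g.auc([1, 0, 1, 0], [0.5, 0.5, 0.5, 0.5], positive_class=1) == 0.5

    def test_reversed_ranking_zero(self):
        assert g.auc([1, 1, 0, 0], [0.1, 0.2, 0.8, 0.9], positive_class=1) == 0.0

    def test_concordant_pair_example(self):
        assert g.auc([1, 0, 1, 0], [0.9, 0.8, 0.7, 0.1], positive_class=1) == pytest.approx(0.75)

    def test_single_class_is_nan(self):
        assert math.isnan(g.auc([1, 1, 1], [0.2, 0.5, 0.9], positive_class=1))

    def test_two_oracle_agreement(self):
        """Rank-statistic AUC equals both sklearn's AUC and the trapezoidal
        area under the empirical ROC on random score sets with ties."""
        rng = np.random.default_rng(2)
        for _ in range(50):
            y = rng.integers(0, 2, 60)
            if y.sum() in (0, 60):
                continue
            s = np.round(rng.random(60), 1)  # coarse grid forces ties
            ours = g.auc(y, s, positive_class=1)
            assert ours == pytest.approx(roc_auc_score(y, s), rel=1e-12)
            fpr, tpr, _ = roc_curve(y, s)
            assert ours == pytest.approx(np.trapezoid(tpr, fpr), rel=1e-12)


class TestReport:
    def test_macro_is_unweighted_mean(self):
        """Per-class SEN 97.44 / 93.02 average to the printed 95.23."""
        assert (0.9744 + 0.9302) / 2 * 100 == pytest.approx(95.23)
        rng = np.random.default_rng(3)
        y = rng.integers(0, 2, 80)
        s = rng.random(80)
        rep = evaluate_scores(y, s)
        assert rep.macro.sen == pytest.approx(
            (rep.per_class["normal"].sen + rep.per_class["glaucoma"].sen) / 2
        )

    def test_both_orientations_reported(self):
        y = ["glaucoma"] * 5 + ["normal"] * 5
        s = [0.9, 0.8, 0.7, 0.4, 0.6, 0.3, 0.2, 0.1, 0.55, 0.45]
        rep = evaluate_scores(y, s)
        assert set(rep.per_class) == {"normal", "glaucoma"}
        assert rep.counts["glaucoma"].TP == rep.counts["normal"].TN

    def test_symmetric_scores_give_equal_class_accuracy(self):
        y = [1, 0]
        s = [0.9, 0.1]
        rep = evaluate_scores(y, s)
        assert rep.per_class["normal"].acc == rep.per_class["glaucoma"].acc == 1.0

    def test_single_class_flags_auc(self):
        rep = evaluate_scores([1, 1, 1], [0.9, 0.8, 0.7])
        assert math.isnan(rep.auc)
        assert "auc" in rep.undefined

    def test_report_many_and_table_format(self):
        rng = np.random.default_rng(4)
        y = rng.integers(0, 2, 40)
        reports = g.report(y, {"a": rng.random(40), "b": rng.random(40)})
        table = g.format_report_table(reports)
        for token in ("Normal", "Glaucoma", "Average", "PREC", "AUC", "a", "b"):
            assert token in table

    def test_json_round_trip(self):
        rng = np.random.default_rng(5)
        y = rng.integers(0, 2, 30)
        rep = evaluate_scores(y, rng.random(30))
        import json

        d = json.loads(rep.to_json())
        assert d["macro"]["sen"] == pytest.approx(rep.macro.sen)
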