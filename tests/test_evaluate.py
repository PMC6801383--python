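"""Median aggregation, ROC/AUC, cutoff selection and the metric suite."""

import math

import numpy as np
import pandas as pd
import pytest

from molsnap.evaluate import (
    MoleculeScore,
    aggregate_median,
    confusion_metrics,
    roc_auc,
    select_cutoff,
)


def _preds(groups):
    rows = []
    for mid, probs in groups.items():
        for k, p in enumerate(probs):
            rows.append((mid, k, 0, 0, p))
    return pd.DataFrame(rows, columns=["mol_id", "rx", "ry", "rz", "probability"])


def _scores(values):
    return [MoleculeScore(f"m{i}", v, 1) for i, v in enumerate(values)]


def _pairs_auc(scores, y):
    """Independent all-pairs rank oracle: P(active > inactive), ties 1/2."""
    s = np.asarray(scores)
    y = np.asarray(y)
    pos, neg = s[y == 1], s[y == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestAggregateMedian:
    def test_odd_count_median(self):
        out = aggregate_median(_preds({"a": [0.2, 0.8, 0.5]}))
        assert out[0].score == pytest.approx(0.5)
        assert out[0].n_images == 3

    def test_even_count_mean_of_central(self):
        out = aggregate_median(_preds({"a": [0.2, 0.4]}))
        assert out[0].score == pytest.approx(0.3)

    def test_order_invariance(self):
        rng = np.random.RandomState(0)
        probs = list(rng.rand(9))
        base = aggregate_median(_preds({"a": probs}))
        shuf = aggregate_median(_preds({"a": list(np.roll(probs, 4))}))
        assert base[0].score == pytest.approx(shuf[0].score)

    def test_empty_table(self):
        assert aggregate_median(_preds({})) == []


class TestRocAuc:
    def test_perfect_separation(self):
        scores = _scores([0.9, 0.9, 0.1, 0.1])
        auc, _ = roc_auc(scores, ["active", "active", "inactive", "inactive"])
        assert auc == pytest.approx(1.0)

    def test_all_ties_gives_half(self):
        scores = _scores([0.5] * 6)
        auc, _ = roc_auc(scores, ["active"] * 3 + ["inactive"] * 3)
        assert auc == pytest.approx(0.5)

    def test_single_inversion_matches_pairs_oracle(self):
        vals = [0.9, 0.8, 0.3, 0.7, 0.2, 0.1]
        y = [1, 1, 1, 0, 0, 0]
        auc, _ = roc_auc(_scores(vals), ["active" if v else "inactive" for v in y])
        assert auc == pytest.approx(_pairs_auc(vals, y))

    def test_trapezoid_equals_rank_oracle_on_random_instances(self):
        """Curve-integral AUC == all-pairs statistic on many random cases."""
        rng = np.random.RandomState(7)
        for _ in range(60):
            n = rng.randint(4, 51)
            y = np.zeros(n, int)
            y[: rng.randint(1, n)] = 1
            rng.shuffle(y)
            if y.sum() in (0, n):
                continue
            vals = np.round(rng.rand(n), 2)  # rounding forces ties
            auc, _ = roc_auc(_scores(vals), ["active" if v else "inactive" for v in y])
            assert auc == pytest.approx(_pairs_auc(vals, y), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc(_scores([0.5, 0.6]), ["active", "active"])

    def test_curve_points_are_roc_coordinates(self):
        scores = _scores([0.9, 0.6, 0.4, 0.1])
        _, curve = roc_auc(scores, ["active", "inactive", "active", "inactive"])
        assert {"fpr", "tpr", "threshold"} <= set(curve.columns)
        assert curve["fpr"].iloc[-1] == 1.0 and curve["tpr"].iloc[-1] == 1.0


class TestSelectCutoff:
    def test_perfect_separation_classifies_all(self):
        vals = [0.9, 0.8, 0.2, 0.1]
        labels = ["active", "active", "inactive", "inactive"]
        t = select_cutoff(_scores(vals), labels)
        assert 0.2 < t < 0.8
        pred = [v >= t for v in vals]
        assert pred == [True, True, False, False]

    def test_all_ties_deterministic(self):
        t1 = select_cutoff(_scores([0.5] * 4), ["active", "active", "inactive", "inactive"])
        t2 = select_cutoff(_scores([0.5] * 4), ["active", "active", "inactive", "inactive"])
        assert t1 == t2

    def test_matches_exhaustive_search_on_small_sets(self):
        """Selected threshold achieves the maximal Youden J found by brute force."""
        rng = np.random.RandomState(3)
        for _ in range(30):
            vals = np.round(rng.rand(6), 2)
            y = np.array([1, 1, 1, 0, 0, 0])
            rng.shuffle(y)
            labels = ["active" if v else "inactive" for v in y]
            t = select_cutoff(_scores(vals), labels)

            def youden(th):
                pred = vals >= th
                sens = (pred & (y == 1)).sum() / 3
                spec = (~pred & (y == 0)).sum() / 3
                return sens + spec - 1

            best = max(youden(th) for th in np.linspace(-0.5, 1.5, 2001))
            assert youden(t) == pytest.approx(best, abs=1e-9)


class TestConfusionMetrics:
    def test_no_false_negatives_gives_sensitivity_one(self):
        m = confusion_metrics(_scores([0.9, 0.9, 0.1]), ["active", "active", "inactive"], 0.5)
        assert m.fn == 0 and m.tp == 2
        assert m.sensitivity == 1.0

    def test_bac_is_mean_of_sensitivity_and_specificity(self):
        # all predicted active: sensitivity 1, specificity 0 -> BAC 0.5
        m = confusion_metrics(_scores([0.9, 0.9]), ["active", "inactive"], 0.1)
        assert m.sensitivity == 1.0 and m.specificity == 0.0
        assert m.bac == 0.5

    def test_mcc_pinned_example(self):
        """tp=3, fp=1, tn=4, fn=2 -> MCC = 10/sqrt(600) with the square-root
        four-factor denominator (the standard definition)."""
        scores = _scores([0.9] * 3 + [0.9] + [0.1] * 4 + [0.1] * 2)
        labels = (["active"] * 3 + ["inactive"] + ["inactive"] * 4 + ["active"] * 2)
        m = confusion_metrics(scores, labels, 0.5)
        assert (m.tp, m.fp, m.tn, m.fn) == (3, 1, 4, 2)
        assert m.mcc == pytest.approx(10 / math.sqrt(600))
        assert m.mcc == pytest.approx(0.4082, abs=1e-4)

    def test_f_equals_p_when_precision_equals_recall(self):
        m = confusion_metrics(
            _scores([0.9, 0.9, 0.1, 0.1]), ["active", "inactive", "active", "inactive"], 0.5
        )
        assert m.precision == m.recall
        assert m.f_value == pytest.approx(m.precision)

    def test_zero_denominator_conventions_flagged(self):
        # nothing predicted active: precision degenerate -> 0, flagged
        m = confusion_metrics(_scores([0.1, 0.2]), ["active", "inactive"], 0.9)
        assert m.precision == 0.0
        assert "precision" in m.degenerate and "mcc" in m.degenerate

    def test_boundary_score_counts_as_active(self):
        m = confusion_metrics(_scores([0.5]), ["active"], 0.5)
        assert m.tp == 1

    def test_counts_sum_to_n(self):
        rng = np.random.RandomState(1)
        vals = rng.rand(20)
        labels = ["active" if v else "inactive" for v in rng.randint(0, 2, 20)]
        m = confusion_metrics(_scores(vals), labels, 0.4)
        assert m.tp + m.fp + m.tn + m.fn == 20

    def test_invariant_under_reordering_and_renaming(self):
        rng = np.random.RandomState(2)
        vals = list(np.round(rng.rand(12), 3))
        y = list(rng.randint(0, 2, 12))
        labels = ["active" if v else "inactive" for v in y]
        a = confusion_metrics(_scores(vals), labels, 0.5)
        order = rng.permutation(12)
        scores_b = [MoleculeScore(f"zz{i}", vals[j], 1) for i, j in enumerate(order)]
        b = confusion_metrics(scores_b, [labels[j] for j in order], 0.5)
        for field in ("bac", "accuracy", "f_value", "mcc"):
            assert getattr(a, field) == pytest.approx(getattr(b, field))

    def test_adding_correct_molecule_never_decreases_accuracy(self):
        vals = [0.9, 0.2, 0.7]
        labels = ["active", "inactive", "inactive"]
        before = confusion_metrics(_scores(vals), labels, 0.5).accuracy
        after = confusion_metrics(_scores(vals + [0.95]), labels + ["active"], 0.5).accuracy
        assert after >= before

    def test_mcc_near_zero_for_label_independent_predictions(self):
        rng = np.random.RandomState(9)
        mccs = []
        for _ in range(200):
            vals = rng.rand(30)
            labels = ["active" if v else "inactive" for v in rng.randint(0, 2, 30)]
            mccs.append(confusion_metrics(_scores(list(vals)), labels, 0.5).mcc)
        assert abs(float(np.mean(mccs))) < 0.05
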