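"""Evaluation metrics: worked table values, identities, oracle cross-checks."""

import numpy as np
import pytest

from leukoscope import metrics_eval as me
from leukoscope.cells import CLASS_NAMES


def random_cm(rng, c=4, max_count=50):
    counts = rng.integers(0, max_count, size=(c, c))
    counts[0, 0] += 1  # ensure non-empty
    return me.ConfusionMatrix(counts=counts, class_names=tuple(CLASS_NAMES[:c]))


class TestConfusionMatrix:
    def test_all_correct_diagonal(self):
        labels = ["eosinophil", "lymphocyte"] * 4
        cm = me.confusion_matrix(labels, labels)
        assert np.trace(cm.counts) == 8
        assert cm.counts.sum() - np.trace(cm.counts) == 0

    def test_direct_small_case(self):
        cm = me.confusion_matrix(["eosinophil", "eosinophil", "lymphocyte"],
                                 ["eosinophil", "lymphocyte", "lymphocyte"],
                                 class_names=("eosinophil", "lymphocyte"))
        assert cm.counts.tolist() == [[1, 1], [0, 1]]

    def test_matches_pairwise_tally(self):
        rng = np.random.default_rng(0)
        t = rng.integers(0, 4, 200)
        p = rng.integers(0, 4, 200)
        cm = me.confusion_matrix(t.tolist(), p.tolist())
        for i in range(4):
            for j in range(4):
                assert cm.counts[i, j] == int(np.sum((t == i) & (p == j)))

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            me.confusion_matrix(["eosinophil"], [])

    def test_unknown_label(self):
        with pytest.raises(ValueError, match="basophil"):
            me.confusion_matrix(["basophil"], ["eosinophil"])


class TestAccuracyKappa:
    def test_perfect_and_uniform(self):
        perfect = me.ConfusionMatrix(np.diag([5, 5, 5, 5]), CLASS_NAMES)
        assert me.accuracy(perfect) == 1.0
        assert me.kappa(perfect).kappa == pytest.approx(1.0)
        uniform = me.ConfusionMatrix(np.array([[25, 25], [25, 25]]),
                                     ("eosinophil", "lymphocyte"))
        assert me.accuracy(uniform) == 0.5
        k = me.kappa(uniform)
        assert (k.p0, k.pe, k.kappa) == (0.5, 0.5, 0.0)

    def test_kappa_hand_computed_three_class(self):
        counts = np.array([[30, 10, 0], [5, 40, 5], [0, 10, 50]])
        cm = me.ConfusionMatrix(counts, CLASS_NAMES[:3])
        n = counts.sum()
        p0 = counts.trace() / n
        pe = sum(counts.sum(1)[i] * counts.sum(0)[i] for i in range(3)) / n**2
        k = me.kappa(cm)
        assert k.kappa == pytest.approx((p0 - pe) / (1 - pe))

    def test_kappa_matches_sklearn(self):
        from sklearn.metrics import cohen_kappa_score

        rng = np.random.default_rng(1)
        t = rng.integers(0, 4, 120)
        p = rng.integers(0, 4, 120)
        cm = me.confusion_matrix(t.tolist(), p.tolist())
        assert me.kappa(cm).kappa == pytest.approx(cohen_kappa_score(t, p))

    def test_degenerate_single_class(self):
        cm = me.ConfusionMatrix(np.array([[7, 0], [0, 0]]),
                                ("eosinophil", "lymphocyte"))
        k = me.kappa(cm)
        assert k.defined and k.kappa == 1.0

    def test_accuracy_trace_over_total(self):
        rng = np.random.default_rng(2)
        cm = random_cm(rng)
        total = 0
        trace = 0
        for i in range(4):
            for j in range(4):
                total += int(cm.counts[i, j])
                if i == j:
                    trace += int(cm.counts[i, j])
        assert me.accuracy(cm) == pytest.approx(trace / total)


class TestPrecisionRecallF1:
    def test_monocyte_worked_example(self):
        """P=0.80, R=1.00 gives F1 = 0.888..., printing as 0.89."""
        f1 = me.f1_score(0.80, 1.00)
        assert f1 == pytest.approx(2 * 0.8 / 1.8)
        assert me.round_half_up(f1) == 0.89

    def test_neutrophil_worked_example(self):
        """P=1.00, R=0.98 prints as F1 = 0.99."""
        assert me.round_half_up(me.f1_score(1.00, 0.98)) == 0.99

    def test_f1_of_equal_rates_is_the_rate(self):
        for p in (0.1, 0.5, 0.93):
            assert me.f1_score(p, p) == pytest.approx(p)

    def test_per_class_matches_sklearn(self):
        from sklearn.metrics import precision_recall_fscore_support

        rng = np.random.default_rng(3)
        t = rng.integers(0, 4, 150)
        p = rng.integers(0, 4, 150)
        cm = me.confusion_matrix(t.tolist(), p.tolist())
        ours = me.per_class_prf(cm)
        sk_p, sk_r, sk_f, _ = precision_recall_fscore_support(
            t, p, labels=range(4), zero_division=0)
        for i, name in enumerate(CLASS_NAMES):
            assert ours[name].precision == pytest.approx(sk_p[i])
            assert ours[name].recall == pytest.approx(sk_r[i])
            assert ours[name].f1 == pytest.approx(sk_f[i])

    def test_zero_division_flagged_not_raised(self):
        cm = me.ConfusionMatrix(np.array([[3, 0], [2, 0]]),
                                ("eosinophil", "lymphocyte"))
        prf = me.per_class_prf(cm)
        assert prf["lymphocyte"].precision == 0.0
        assert prf["lymphocyte"].precision_undefined

    def test_macro_precision_worked_example(self):
        """Per-class precisions (1.00, 1.00, 0.80, 1.00) average to 0.95."""
        per = {n: me.ClassPRF(p, 1.0, me.f1_score(p, 1.0), 10)
               for n, p in zip(CLASS_NAMES, (1.00, 1.00, 0.80, 1.00))}
        mp, mr, mf = me.macro_scores(per)
        assert mp == pytest.approx(0.95)
        assert mr == pytest.approx(1.0)

    def test_macro_equals_loop_mean(self):
        rng = np.random.default_rng(4)
        cm = random_cm(rng)
        per = me.per_class_prf(cm)
        mp, mr, mf = me.macro_scores(per)
        assert mp == pytest.approx(sum(c.precision for c in per.values()) / 4)
        assert mf == pytest.approx(sum(c.f1 for c in per.values()) / 4)


class TestMicroF1:
    def test_equals_accuracy_on_random_matrices(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            cm = random_cm(rng)
            assert me.micro_f1(cm) == pytest.approx(me.accuracy(cm))

    def test_perfect(self):
        cm = me.ConfusionMatrix(np.diag([3, 3, 3, 3]), CLASS_NAMES)
        assert me.micro_f1(cm) == 1.0


class TestRocAuc:
    def test_perfectly_separated(self):
        scores = np.array([[0.9, 0.1], [0.8, 0.2], [0.2, 0.8], [0.1, 0.9]])
        roc = me.roc_auc(scores, [0, 0, 1, 1], class_names=("eosinophil", "lymphocyte"))
        assert roc["eosinophil"].auc == pytest.approx(1.0)
        assert roc["lymphocyte"].auc == pytest.approx(1.0)

    def test_constant_scores_half(self):
        scores = np.full((10, 2), 0.5)
        roc = me.roc_auc(scores, [0] * 5 + [1] * 5,
                         class_names=("eosinophil", "lymphocyte"))
        assert roc["eosinophil"].auc == pytest.approx(0.5)

    def test_single_class_flagged_undefined(self):
        scores = np.full((4, 2), 0.5)
        roc = me.roc_auc(scores, [0, 0, 0, 0], class_names=("eosinophil", "lymphocyte"))
        assert not roc["lymphocyte"].defined

    def test_equals_mann_whitney_concordance(self):
        """AUC == concordant pairs / (n+ * n-) with half credit for ties."""
        rng = np.random.default_rng(6)
        t = rng.integers(0, 2, 20)
        t[:2] = [0, 1]
        s = np.round(rng.random(20), 1)  # coarse grid to force ties
        scores = np.stack([1 - s, s], axis=1)
        roc = me.roc_auc(scores, t.tolist(), class_names=("eosinophil", "lymphocyte"))
        pos = s[t == 1]
        neg = s[t == 0]
        conc = sum((p > n_) + 0.5 * (p == n_) for p in pos for n_ in neg)
        assert roc["lymphocyte"].auc == pytest.approx(conc / (len(pos) * len(neg)))

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(7)
        t = (rng.random(30) > 0.5).astype(int)
        t[:2] = [0, 1]
        s = rng.random(30)
        a1 = me.roc_auc(np.stack([1 - s, s], 1), t.tolist(),
                        class_names=("eosinophil", "lymphocyte"))["lymphocyte"].auc
        s2 = np.exp(5 * s)  # strictly monotone
        a2 = me.roc_auc(np.stack([-s2, s2], 1), t.tolist(),
                        class_names=("eosinophil", "lymphocyte"))["lymphocyte"].auc
        assert a1 == pytest.approx(a2)

    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(8)
        t = rng.integers(0, 4, 60)
        scores = rng.dirichlet(np.ones(4), size=60)
        roc = me.roc_auc(scores, t.tolist())
        for i, name in enumerate(CLASS_NAMES):
            sk = roc_auc_score((t == i).astype(int), scores[:, i])
            assert roc[name].auc == pytest.approx(sk)


class TestEvaluateReport:
    def _oracle_model(self, correct=True):
        """A stub model that predicts the true (or always-wrong) class."""

        class Stub:
            class config:
                input_side = 64
                n_classes = 4

        return Stub()

    def test_report_internal_consistency(self, small_dataset):
        from leukoscope.dense_model import DenseNetConfig, build_model

        model = build_model(DenseNetConfig(seed=1))
        report = me.evaluate(model, small_dataset)
        cm = report.confusion
        assert report.accuracy == pytest.approx(me.accuracy(cm))
        assert report.micro_f1 == pytest.approx(me.micro_f1(cm))
        per = me.per_class_prf(cm)
        for name in CLASS_NAMES:
            assert report.per_class[name].f1 == pytest.approx(per[name].f1)
        assert cm.total == len(small_dataset)

    def test_oracle_predictions_perfect_report(self):
        labels = [i % 4 for i in range(40)]
        cm = me.confusion_matrix(labels, labels)
        scores = np.eye(4)[labels]
        report = me.report_from_counts(cm, scores=scores, true_labels=labels)
        assert report.accuracy == 1.0
        assert report.kappa.kappa == pytest.approx(1.0)
        for name in CLASS_NAMES:
            assert report.roc[name].auc == pytest.approx(1.0)

    def test_antagonist_two_class(self):
        t = [0, 1] * 10
        p = [1, 0] * 10
        cm = me.confusion_matrix(t, p, class_names=("eosinophil", "lymphocyte"))
        report = me.report_from_counts(cm)
        assert report.accuracy == 0.0
        assert report.kappa.kappa <= 0.0

    def test_table_frame_layout(self):
        labels = [i % 4 for i in range(40)]
        cm = me.confusion_matrix(labels, labels)
        report = me.report_from_counts(cm)
        df = report.table_frame()
        assert list(df.columns) == ["class", "precision", "recall", "f1-score"]
        assert list(df["class"]) == list(CLASS_NAMES) + ["accuracy", "macro avg",
                                                         "weighted avg"]

    def test_json_roundtrip(self, tmp_path):
        import json

        labels = [i % 4 for i in range(20)]
        cm = me.confusion_matrix(labels, labels)
        report = me.report_from_counts(cm)
        report.write_json(tmp_path / "r.json")
        data = json.loads((tmp_path / "r.json").read_text())
        assert data["accuracy"] == 1.0
        assert data["kappa"]["kappa"] == 1.0


class TestRounding:
    @pytest.mark.parametrize("x,expected", [(0.888, 0.89), (0.985, 0.99),
                                            (0.125, 0.13), (0.994, 0.99)])
    def test_half_up(self, x, expected):
        assert me.round_half_up(x) == expected
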