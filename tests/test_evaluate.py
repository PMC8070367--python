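"""Confusion matrices, macro metrics, the MLB baseline, and split schemes."""

from collections import Counter

import numpy as np
import pytest

from rtname import evaluate as ev
from rtname.datatypes import LabelSet, PROSTATE_LABELS

from _oracles import metrics_tally

LS3 = LabelSet(("A", "B", "other"))


class TestConfusion:
    def test_perfect_predictions_are_diagonal(self):
        truth = ["A", "B", "other", "A"]
        cm = ev.confusion(truth, truth, LS3)
        assert np.array_equal(cm.counts, np.diag([2, 1, 1]))

    def test_counts_by_enumeration(self):
        cm = ev.confusion(["A", "A", "B"], ["A", "B", "B"], LS3)
        expected = np.zeros((3, 3), dtype=int)
        expected[0, 0] = 1
        expected[0, 1] = 1
        expected[1, 1] = 1
        assert np.array_equal(cm.counts, expected)

    def test_total_equals_input_length(self, rng):
        for _ in range(20):
            n = int(rng.integers(1, 50))
            truth = rng.choice(LS3.class_names, n).tolist()
            pred = rng.choice(LS3.class_names, n).tolist()
            assert ev.confusion(truth, pred, LS3).total == n

    def test_unknown_label_rejected(self):
        with pytest.raises(KeyError):
            ev.confusion(["A"], ["Z"], LS3)


class TestMetrics:
    def test_perfect_predictions_score_one(self):
        cm = ev.confusion(["A", "B", "other"], ["A", "B", "other"], LS3)
        rep = ev.compute_metrics(cm)
        assert rep.macro_precision == rep.macro_recall == rep.macro_f1 == rep.accuracy == 1.0

    def test_matches_tally_oracle_on_random_matrices(self, rng):
        for _ in range(50):
            n = int(rng.integers(2, 9))
            ls = LabelSet(tuple(f"c{i}" for i in range(n - 1)) + ("other",))
            counts = rng.integers(0, 20, size=(n, n))
            if counts.sum() == 0:
                counts[0, 0] = 1
            cm = ev.ConfusionMatrix(counts, ls)
            rep = ev.compute_metrics(cm)
            p, r, f, a = metrics_tally(counts)
            assert abs(rep.macro_precision - p) < 1e-12
            assert abs(rep.macro_recall - r) < 1e-12
            assert abs(rep.macro_f1 - f) < 1e-12
            assert abs(rep.accuracy - a) < 1e-12

    def test_accuracy_is_trace_over_total(self, rng):
        counts = rng.integers(0, 30, size=(3, 3)) + 1
        rep = ev.compute_metrics(ev.ConfusionMatrix(counts, LS3))
        assert rep.accuracy == pytest.approx(np.trace(counts) / counts.sum())

    def test_absent_labels_excluded_from_macro_average(self):
        # class B never appears in truth or predictions -> N = 2
        cm = ev.confusion(["A", "other", "A"], ["A", "other", "other"], LS3)
        rep = ev.compute_metrics(cm)
        assert rep.evaluated_label_count == 2
        assert "B" not in rep.per_class


class TestMajorityBaseline:
    def test_predicts_most_frequent_training_label(self):
        mlb = ev.majority_label_baseline(["other"] * 3 + ["A"], LS3)
        assert mlb.label == "other"
        assert mlb.predict([1, 2, 3]) == ["other"] * 3

    def test_tie_breaks_by_labelset_order(self):
        mlb = ev.majority_label_baseline(["B", "A"], LS3)
        assert mlb.label == "A"

    def test_closed_form_metrics_for_constant_predictor(self):
        # majority fraction a = 0.78 over 6 evaluated labels
        truth = ["other"] * 78 + ["A"] * 22
        ls6 = LabelSet(("A", "B", "C", "D", "E", "other"))
        truth = (["other"] * 78 + ["A"] * 5 + ["B"] * 5 + ["C"] * 4 + ["D"] * 4 + ["E"] * 4)
        mlb = ev.majority_label_baseline(truth, ls6)
        rep = ev.compute_metrics(ev.confusion(truth, mlb.predict(truth), ls6))
        a, n = 0.78, 6
        assert rep.macro_precision == pytest.approx(a / n)
        assert rep.macro_recall == pytest.approx(1 / n)
        assert rep.macro_f1 == pytest.approx((2 * a / (1 + a)) / n)
        assert rep.accuracy == pytest.approx(a)


class TestSplits:
    def test_kfold_exact_divisibility(self):
        ids = np.arange(100)
        labels = ["x"] * 80 + ["other"] * 20
        plan = ev.stratified_kfold(ids, labels, k=5, seed=1)
        for split in plan.splits:
            val_labels = [labels[i] for i in split["validation"]]
            assert Counter(val_labels) == {"x": 16, "other": 4}

    def test_kfold_folds_partition_the_records(self, rng):
        ids = np.arange(57)
        labels = rng.choice(["a", "b", "other"], 57).tolist()
        plan = ev.stratified_kfold(ids, labels, k=4, seed=2)
        seen = []
        for split in plan.splits:
            assert set(split["train"]).isdisjoint(split["validation"])
            assert sorted(split["train"] + split["validation"]) == list(range(57))
            seen.extend(split["validation"])
        assert sorted(seen) == list(range(57))

    def test_kfold_seed_determinism(self):
        ids = np.arange(30)
        labels = (["a"] * 15 + ["b"] * 15)
        p1 = ev.stratified_kfold(ids, labels, k=3, seed=7)
        p2 = ev.stratified_kfold(ids, labels, k=3, seed=7)
        assert p1.splits == p2.splits

    def test_kfold_k_larger_than_records_rejected(self):
        with pytest.raises(ValueError):
            ev.stratified_kfold(np.arange(3), ["a", "b", "a"], k=5)

    def test_center_loo_each_record_validated_once(self):
        ids = np.arange(12)
        centers = np.repeat(["C0", "C1", "C2"], 4)
        plan = ev.center_cross_validation(ids, centers)
        assert len(plan.splits) == 3
        validated = sorted(i for s in plan.splits for i in s["validation"])
        assert validated == list(range(12))
        for s in plan.splits:
            assert sorted(s["train"] + s["validation"]) == list(range(12))

    def test_center_loo_two_centers_are_complementary(self):
        plan = ev.center_cross_validation(np.arange(4), np.array(["X", "X", "Y", "Y"]))
        assert plan.splits[0]["validation"] == [0, 1]
        assert plan.splits[1]["validation"] == [2, 3]

    def test_center_loo_single_center_rejected(self):
        with pytest.raises(ValueError):
            ev.center_cross_validation(np.arange(3), np.array(["X"] * 3))

    def test_holdout_no_center_straddles(self):
        ids = np.arange(40)
        centers = np.repeat([f"C{i}" for i in range(8)], 5)
        plan = ev.center_holdout(ids, centers, n_test_centers=2, seed=4)
        split = plan.splits[0]
        train_centers = {centers[i] for i in split["train"]}
        test_centers = {centers[i] for i in split["test"]}
        assert train_centers.isdisjoint(test_centers)
        assert len(test_centers) == 2

    def test_holdout_seed_determinism_and_validation(self):
        ids = np.arange(10)
        centers = np.repeat(["A", "B"], 5)
        p1 = ev.center_holdout(ids, centers, 1, seed=0)
        p2 = ev.center_holdout(ids, centers, 1, seed=0)
        assert p1.splits == p2.splits
        with pytest.raises(ValueError):
            ev.center_holdout(ids, centers, 2, seed=0)


def test_confusion_heatmap_renders(tmp_path):
    cm = ev.confusion(["A", "B"], ["A", "B"], LS3)
    out = tmp_path / "cm.png"
    ev.plot_confusion(cm, out, title="toy")
    assert out.stat().st_size > 0


def test_mlb_probability_vector_layout():
    mlb = ev.majority_label_baseline(["other"], PROSTATE_LABELS)
    proba = mlb.predict_proba([0, 1])
    assert proba.shape == (2, 8)
    assert np.allclose(proba[:, PROSTATE_LABELS.index("other")], 1.0)
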