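"""Metrics against brute-force oracles; fold construction; classifier harness."""

import numpy as np
import pytest

import falldetect as fd
from falldetect.evaluation import ConfusionMatrix, predict_with_scores


def brute_force_macro(cm: ConfusionMatrix):
    """Oracle: literally materialize one binary confusion matrix per class."""
    C = len(cm.classes)
    se, sp, f1 = [], [], []
    for i in range(C):
        tp = fp = fn = tn = 0
        for t in range(C):
            for p in range(C):
                k = cm.counts[t, p]
                if t == i and p == i:
                    tp += k
                elif t == i:
                    fn += k
                elif p == i:
                    fp += k
                else:
                    tn += k
        se.append(tp / (tp + fn) if tp + fn else 0.0)
        sp.append(tn / (tn + fp) if tn + fp else 0.0)
        f1.append(2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0)
    return np.mean(se), np.mean(sp), np.mean(f1)


def brute_force_auroc(scores, is_pos):
    """Oracle: exhaustive positive-negative pair counting, ties worth 1/2."""
    pos = scores[is_pos]
    neg = scores[~is_pos]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestFolds:
    def test_20_subjects_5_folds_gives_4_test_subjects(self):
        subjects = [f"SA{i:02d}" for i in range(1, 21)]
        folds = fd.make_subject_folds(subjects, k=5, seed=0)
        for f in range(5):
            assert len(folds.test_subjects(f)) == 4
            assert len(folds.train_subjects(f)) == 16

    def test_train_test_disjoint_and_partition(self):
        subjects = [f"S{i}" for i in range(13)]
        folds = fd.make_subject_folds(subjects, k=5, seed=1)
        all_test = []
        for f in range(5):
            test = folds.test_subjects(f)
            assert not set(test) & set(folds.train_subjects(f))
            all_test.extend(test)
        assert sorted(all_test) == sorted(subjects)

    def test_deterministic_per_seed(self):
        subjects = [f"S{i}" for i in range(10)]
        a = fd.make_subject_folds(subjects, k=5, seed=42)
        b = fd.make_subject_folds(subjects, k=5, seed=42)
        c = fd.make_subject_folds(subjects, k=5, seed=43)
        assert a.assignments == b.assignments
        assert a.assignments != c.assignments

    def test_k_exceeding_subjects_rejected(self):
        with pytest.raises(ValueError):
            fd.make_subject_folds(["a", "b"], k=5, seed=0)


class TestBinaryMetrics:
    def test_hand_computed(self):
        # TN=8, FP=2 / FN=1, TP=9 with FALL (second class) positive
        cm = ConfusionMatrix(("ADL", "FALL"), np.array([[8, 2], [1, 9]]))
        m = fd.binary_metrics(cm)
        assert m.sensitivity == pytest.approx(0.9)
        assert m.specificity == pytest.approx(0.8)
        assert m.accuracy == pytest.approx(0.85)
        assert m.f1 == pytest.approx(18 / 21)

    def test_perfect_classifier(self):
        cm = ConfusionMatrix(("ADL", "FALL"), np.array([[5, 0], [0, 5]]))
        m = fd.binary_metrics(cm)
        assert (m.sensitivity, m.specificity, m.accuracy, m.f1) == (1, 1, 1, 1)

    def test_all_positive_predictor(self):
        cm = ConfusionMatrix(("ADL", "FALL"), np.array([[0, 5], [0, 5]]))
        m = fd.binary_metrics(cm)
        assert m.sensitivity == 1.0
        assert m.specificity == 0.0
        assert m.accuracy == 0.5

    def test_zero_denominator_yields_zero(self):
        cm = ConfusionMatrix(("ADL", "FALL"), np.array([[3, 0], [0, 0]]))
        m = fd.binary_metrics(cm)
        assert m.sensitivity == 0.0  # no positives at all


class TestMacroMetrics:
    def test_diagonal_matrix_is_perfect(self):
        cm = ConfusionMatrix(tuple("abcd"), np.diag([3, 7, 2, 9]))
        m = fd.macro_metrics(cm)
        assert (m.sensitivity, m.specificity, m.f1) == (1.0, 1.0, 1.0)

    def test_uniform_matrix(self):
        cm = ConfusionMatrix(tuple("abcd"), np.full((4, 4), 5))
        m = fd.macro_metrics(cm)
        assert m.sensitivity == pytest.approx(0.25)
        assert m.accuracy == pytest.approx(0.25)

    def test_two_class_macro_reduces_to_mean_of_per_class_sensitivity(self):
        counts = np.array([[8, 2], [1, 9]])
        cm = ConfusionMatrix(("n", "p"), counts)
        m = fd.macro_metrics(cm)
        assert m.sensitivity == pytest.approx((8 / 10 + 9 / 10) / 2)

    @pytest.mark.parametrize("n_classes", [2, 3, 4])
    def test_matches_brute_force_oracle(self, n_classes, rng):
        for _ in range(50):
            counts = rng.integers(0, 30, size=(n_classes, n_classes))
            cm = ConfusionMatrix(tuple(map(str, range(n_classes))), counts)
            m = fd.macro_metrics(cm)
            ose, osp, of1 = brute_force_macro(cm)
            assert m.sensitivity == pytest.approx(ose, abs=1e-12)
            assert m.specificity == pytest.approx(osp, abs=1e-12)
            assert m.f1 == pytest.approx(of1, abs=1e-12)

    def test_accuracy_is_trace_over_total(self, rng):
        counts = rng.integers(1, 30, size=(4, 4))
        cm = ConfusionMatrix(tuple("abcd"), counts)
        assert fd.macro_metrics(cm).accuracy == pytest.approx(
            np.trace(counts) / counts.sum()
        )


class TestAuroc:
    def test_perfect_separation(self):
        labels = ["n"] * 3 + ["p"] * 3
        scores = np.array([0.1, 0.2, 0.3, 0.7, 0.8, 0.9])
        assert fd.auroc(scores, labels, ("n", "p")) == 1.0

    def test_uninformative_scores(self):
        labels = ["n", "n", "p", "p"]
        assert fd.auroc(np.ones(4), labels, ("n", "p")) == pytest.approx(0.5)

    def test_six_sample_toy_matches_pair_counting(self):
        scores = np.array([0.1, 0.4, 0.35, 0.8, 0.35, 0.9])
        labels = np.array(["n", "p", "n", "p", "p", "n"])
        got = fd.auroc(scores, labels, ("n", "p"))
        assert got == pytest.approx(brute_force_auroc(scores, labels == "p"))

    def test_random_sets_match_pair_counting(self, rng):
        for _ in range(50):
            n = rng.integers(4, 50)
            scores = rng.choice(np.linspace(0, 1, 11), size=n)
            labels = rng.choice(["n", "p"], size=n)
            if len(set(labels)) < 2:
                continue
            got = fd.auroc(scores, labels, ("n", "p"))
            want = brute_force_auroc(scores, labels == "p")
            assert got == pytest.approx(want, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fd.auroc(np.ones(3), ["p", "p", "p"], ("n", "p"))

    def test_macro_multiclass_is_mean_of_one_vs_rest(self, rng):
        n = 40
        classes = ("a", "b", "c")
        labels = rng.choice(classes, size=n)
        scores = rng.random((n, 3))
        got = fd.auroc(scores, labels, classes)
        want = np.mean(
            [brute_force_auroc(scores[:, i], labels == c) for i, c in enumerate(classes)]
        )
        assert got == pytest.approx(want, abs=1e-12)


@pytest.fixture(scope="module")
def separable():
    rng = np.random.default_rng(0)
    X0 = rng.normal(0, 0.3, size=(40, 5))
    X1 = rng.normal(3, 0.3, size=(40, 5))
    X = np.vstack([X0, X1])
    y = np.array(["ADL"] * 40 + ["FALL"] * 40)
    return X, y


class TestClassifierHarness:
    @pytest.mark.parametrize("name", fd.ALGORITHMS)
    def test_training_accuracy_on_separable_data(self, name, separable):
        X, y = separable
        model = fd.train_classifier(name, X, y, seed=0)
        assert (model.predict(X) == y).mean() == 1.0

    def test_knn_k1_nearest_self(self, separable):
        X, y = separable
        model = fd.train_classifier("KNN", X, y, params={"n_neighbors": 1})
        assert (model.predict(X) == y).all()

    @pytest.mark.parametrize("name", ["RF", "GB"])
    def test_stochastic_learners_reproducible_with_seed(self, name, separable):
        X, y = separable
        rng = np.random.default_rng(1)
        X_test = rng.normal(1.5, 1.0, size=(30, 5))
        a = fd.train_classifier(name, X, y, seed=7).predict(X_test)
        b = fd.train_classifier(name, X, y, seed=7).predict(X_test)
        np.testing.assert_array_equal(a, b)

    def test_unknown_algorithm_rejected(self, separable):
        with pytest.raises(ValueError, match="unknown algorithm"):
            fd.train_classifier("MLP", *separable)

    def test_svm_scores_align_with_classes(self, rng):
        X = np.vstack([rng.normal(i, 0.2, size=(20, 3)) for i in range(4)])
        y = np.repeat(list(fd.PHASE_CLASSES), 20)
        model = fd.train_classifier("SVM", X, y)
        _, scores = predict_with_scores(model, X, fd.PHASE_CLASSES)
        assert scores.shape == (80, 4)
        # the column of the true class should carry the highest score
        assert (np.argmax(scores, axis=1) == np.repeat(np.arange(4), 20)).mean() > 0.95


@pytest.fixture(scope="module")
def small_features(prepared50):
    return fd.extract_features(prepared50)


class TestCrossValidate:
    def test_confusion_totals_conserved(self, small_features):
        folds = fd.make_subject_folds(small_features["subject"], k=5, seed=0)
        report = fd.cross_validate(
            small_features, "DT", folds, classes=("ADL", "FALL"), seed=0
        )
        assert sum(f.cm.total for f in report.folds) == len(small_features)

    def test_row_order_does_not_change_metrics(self, small_features):
        folds = fd.make_subject_folds(small_features["subject"], k=5, seed=0)
        shuffled = small_features.sample(frac=1.0, random_state=3).reset_index(drop=True)
        a = fd.cross_validate(small_features, "KNN", folds, classes=("ADL", "FALL"))
        b = fd.cross_validate(shuffled, "KNN", folds, classes=("ADL", "FALL"))
        for fa, fb in zip(a.folds, b.folds):
            np.testing.assert_array_equal(fa.cm.counts, fb.cm.counts)

    def test_no_test_subject_in_training(self, small_features):
        folds = fd.make_subject_folds(small_features["subject"], k=5, seed=0)
        report = fd.cross_validate(small_features, "DT", folds, classes=("ADL", "FALL"))
        seen = set()
        for f in report.folds:
            assert not set(f.test_subjects) & set(folds.train_subjects(f.fold))
            seen.update(f.test_subjects)
        assert seen == set(small_features["subject"])

    def test_report_serializes_to_json(self, small_features, tmp_path):
        folds = fd.make_subject_folds(small_features["subject"], k=5, seed=0)
        report = fd.cross_validate(small_features, "DT", folds, classes=("ADL", "FALL"))
        path = report.to_json(tmp_path / "report.json")
        import json

        payload = json.loads(path.read_text())
        assert payload["algorithm"] == "DT"
        assert len(payload["folds"]) == 5
        assert "accuracy" in payload["summary"]
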