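import numpy as np
import pytest

from semgkit.evaluate import (
    ConfusionMatrix,
    PipelineConfig,
    cross_validate,
    kruskal_wallis_screen,
    metrics_from_confusion,
    sweep_basis,
    sweep_dimension,
    sweep_noise,
    sweep_window,
)
from semgkit.synthetic import SyntheticSpec, generate

FAST = PipelineConfig(basis="db4")  # short filter: fast feature extraction


class TestConfusionMetrics:
    def test_perfect_classifier(self):
        cm = ConfusionMatrix(counts=np.array([[5, 0], [0, 5]]), classes=("A", "B"))
        t = metrics_from_confusion(cm)
        assert np.allclose(t.values, 1.0)
        assert cm.overall_accuracy == 1.0

    def test_hand_worked_two_class_example(self):
        cm = ConfusionMatrix(counts=np.array([[3, 1], [2, 4]]), classes=("A", "B"))
        t = metrics_from_confusion(cm)
        a = t.loc["A"]
        assert a["recall"] == pytest.approx(0.75)
        assert a["precision"] == pytest.approx(0.6)
        assert a["accuracy"] == pytest.approx(0.7)
        assert a["f1"] == pytest.approx(2 * 0.75 * 0.6 / 1.35)

    def test_absent_class_warns_with_zero_recall(self):
        cm = ConfusionMatrix(counts=np.array([[0, 0], [1, 9]]), classes=("A", "B"))
        with pytest.warns(UserWarning, match="absent"):
            t = metrics_from_confusion(cm)
        assert t.loc["A", "recall"] == 0.0

    def test_empty_matrix_errors(self):
        cm = ConfusionMatrix(counts=np.zeros((2, 2), dtype=int), classes=("A", "B"))
        with pytest.raises(ValueError):
            metrics_from_confusion(cm)

    def test_agrees_with_per_sample_counter(self, rng):
        """Brute-force oracle: count TP/TN/FP/FN per class sample by sample."""
        classes = ("A", "B", "C")
        y_true = rng.choice(classes, size=300)
        y_pred = rng.choice(classes, size=300)
        cm = ConfusionMatrix.from_predictions(y_true, y_pred, classes)
        table = metrics_from_confusion(cm)
        for ci, c in enumerate(classes):
            tp = np.sum((y_true == c) & (y_pred == c))
            tn = np.sum((y_true != c) & (y_pred != c))
            fp = np.sum((y_true != c) & (y_pred == c))
            fn = np.sum((y_true == c) & (y_pred != c))
            assert table.loc[c, "accuracy"] == pytest.approx((tp + tn) / 300)
            assert table.loc[c, "recall"] == pytest.approx(tp / (tp + fn))
            assert table.loc[c, "precision"] == pytest.approx(
                tp / (tp + fp) if tp + fp else 0.0
            )


class TestCrossValidate:
    def test_deterministic_given_seed(self, small_trial_set):
        r1 = cross_validate(small_trial_set, FAST, n_folds=4, seed=9)
        r2 = cross_validate(small_trial_set, FAST, n_folds=4, seed=9)
        assert np.array_equal(r1.confusion.counts, r2.confusion.counts)
        assert r1.fold_assignments == r2.fold_assignments

    def test_confusion_total_counts_every_window(self, small_trial_set):
        r = cross_validate(small_trial_set, FAST, n_folds=4, seed=9)
        n_windows = len(small_trial_set) * (3000 // 400)
        assert r.confusion.total == n_windows
        assert r.overall_accuracy == pytest.approx(
            np.trace(r.confusion.counts) / n_windows
        )

    def test_trial_grouping_holds(self, small_trial_set):
        r = cross_validate(small_trial_set, FAST, n_folds=4, seed=9)
        # one fold per trial; stratified: every fold contains every class
        folds = {}
        for key, f in r.fold_assignments.items():
            folds.setdefault(f, []).append(key)
        assert len(folds) == 4

    def test_fewer_trials_than_folds_errors(self):
        spec = SyntheticSpec(n_subjects=1, n_trials_per_class=2, seed=0)
        with pytest.raises(ValueError, match="fewer"):
            cross_validate(generate(spec), FAST, n_folds=3, seed=0)

    def test_chance_level_on_unseparable_classes(self):
        """With separation 0 the classes are generatively identical, so
        accuracy must sit at chance; this doubles as the leakage check,
        because any train/test window leakage from shared trials would
        pull accuracy above 1/6."""
        spec = SyntheticSpec(n_subjects=1, n_trials_per_class=8,
                             separation=0.0, seed=13)
        r = cross_validate(generate(spec), FAST, n_folds=4, seed=13)
        n_trials = 48
        se = np.sqrt((1 / 6) * (5 / 6) / n_trials)
        assert abs(r.overall_accuracy - 1 / 6) < 3 * se


@pytest.fixture(scope="module")
def trial_set():
    spec = SyntheticSpec(n_subjects=1, n_trials_per_class=6,
                         separation=2.0, seed=17)
    return generate(spec)


class TestSweeps:
    def test_basis_sweep_shape_and_bounds(self, trial_set):
        df = sweep_basis(trial_set, FAST, bases=("db4", "sym3"),
                         classifiers=("knn",), n_folds=3, seed=3)
        assert df.shape == (1, 2)
        assert ((df.values >= 0) & (df.values <= 1)).all()

    def test_dimension_sweep(self, trial_set):
        df = sweep_dimension(trial_set, FAST, dims=(10, 30),
                             classifiers=("knn",), n_folds=3, seed=3)
        assert df.shape == (1, 2)
        with pytest.raises(ValueError, match="exceeds"):
            sweep_dimension(trial_set, FAST, dims=(65,), classifiers=("knn",),
                            n_folds=3, seed=3)

    def test_noise_sweep_degrades_with_noise(self, trial_set):
        df = sweep_noise(trial_set, FAST, levels=(1e-2, 8e-1),
                         classifiers=("knn",), n_folds=3, seed=3)
        assert df.shape == (1, 2)
        assert df.loc["knn", 8e-1] <= df.loc["knn", 1e-2]

    def test_noise_sweep_scale_consistency(self, trial_set):
        """Scaling signals and reference magnitude by the same factor
        leaves accuracies unchanged."""
        from semgkit.signal_io import Recording

        scaled = [
            Recording(samples=10.0 * r.samples, rate=r.rate, label=r.label,
                      subject=r.subject, trial=r.trial)
            for r in trial_set
        ]
        a = sweep_noise(trial_set, FAST, levels=(1e-1,), classifiers=("knn",),
                        reference_magnitude=1.0, n_folds=3, seed=3)
        b = sweep_noise(scaled, FAST, levels=(1e-1,), classifiers=("knn",),
                        reference_magnitude=10.0, n_folds=3, seed=3)
        assert a.loc["knn", 1e-1] == pytest.approx(b.loc["knn", 1e-1], abs=1e-12)

    def test_window_sweep(self, trial_set):
        df = sweep_window(trial_set, FAST, sizes=(200, 400),
                          classifiers=("knn",), n_folds=3, seed=3)
        assert df.shape == (1, 2)
        with pytest.raises(ValueError, match="exceeds"):
            sweep_window(trial_set, FAST, sizes=(4000,), classifiers=("knn",))


class TestKruskalWallis:
    def test_two_separated_groups_hand_example(self):
        X = np.array([[1.0], [2.0], [3.0], [10.0], [11.0], [12.0]])
        labels = np.array(["a", "a", "a", "b", "b", "b"])
        t = kruskal_wallis_screen(X, labels)
        assert t.loc[0, "H"] == pytest.approx(3.857142857, rel=1e-9)
        assert t.loc[0, "p"] == pytest.approx(0.0495346, rel=1e-4)

    def test_identical_distributions_give_zero_h(self):
        X = np.array([[1.0], [2.0], [3.0], [1.0], [2.0], [3.0]])
        labels = np.array(["a", "a", "a", "b", "b", "b"])
        t = kruskal_wallis_screen(X, labels)
        assert t.loc[0, "H"] == pytest.approx(0.0, abs=1e-12)

    def test_constant_column_warns(self):
        X = np.ones((6, 1))
        labels = np.array(["a", "a", "a", "b", "b", "b"])
        with pytest.warns(UserWarning, match="constant"):
            t = kruskal_wallis_screen(X, labels)
        assert t.loc[0, "H"] == 0.0 and t.loc[0, "p"] == 1.0

    def test_separated_synthetic_components_are_significant(self, small_trial_set):
        """On well-separated classes, retained principal components show
        p < 0.001 in the rank test."""
        from semgkit.dimred import pca_fit, pca_transform
        from semgkit.features import build_feature_matrix
        from semgkit.signal_io import segment

        windows = []
        for rec in small_trial_set:
            windows.extend(segment(rec, 400))
        fm = build_feature_matrix(windows, basis="db4", level=3)
        pca = pca_fit(fm.values, k=5)
        Y = pca_transform(pca, fm.values)
        t = kruskal_wallis_screen(Y, fm.labels)
        assert (t["p"] < 0.001).all()

    def test_group_size_validation(self):
        with pytest.raises(ValueError):
            kruskal_wallis_screen(np.ones((3, 1)), np.array(["a", "a", "a"]))
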