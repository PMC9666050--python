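"""Cross-validated evaluation and the four experimental sweeps.

Validation protocol.  The pipeline (PCA fitted on training windows only,
then a classifier, with any z-scoring likewise fitted on the training
fold) is evaluated with stratified k-fold cross-validation **grouped by
trial**: all windows cut from one trial land in the same fold, because
adjacent windows of a trial are strongly correlated and splitting them
across folds would leak test information into training.  By default
each subject is evaluated separately and the confusions are pooled
(common practice for subject-specific myoelectric control); a pooled
mode that mixes subjects in one model is available.

Metrics are one-vs-rest per class: with TP/TN/FP/FN counted by treating
one class as positive,

    accuracy  = (TP + TN) / (TP + TN + FN + FP)
    recall    = TP / (TP + FN)
    precision = TP / (TP + FP)
    F1        = 2 * recall * precision / (recall + precision)

The sweep runners re-run the cross-validation over a grid of wavelet
bases, PCA dimensions, additive test-noise levels (train on clean
windows, perturb only the test windows and re-extract their features),
and window sizes, emitting one accuracy table per sweep.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from typing import Any, Callable

import numpy as np
import pandas as pd
import scipy.stats

from . import classify
from .features import build_feature_matrix, extract_features, FeatureMatrix
from .signal_io import Recording, Window, segment
from .dimred import pca_fit, pca_transform

__all__ = [
    "PipelineConfig",
    "ConfusionMatrix",
    "EvaluationReport",
    "metrics_from_confusion",
    "cross_validate",
    "sweep_basis",
    "sweep_dimension",
    "sweep_noise",
    "sweep_window",
    "kruskal_wallis_screen",
]

DEFAULT_BASES = ("sym3", "fk8", "dmey", "db4", "coif2")
DEFAULT_DIMS = (10, 20, 30, 40, 50)
DEFAULT_NOISE_LEVELS = (1e-2, 1e-1, 3e-1, 5e-1, 8e-1)
DEFAULT_WINDOW_SIZES = (200, 250, 300, 350, 400)
DEFAULT_CLASSIFIERS = ("knn", "svm", "bagging")


@dataclass
class PipelineConfig:
    """Full parameter record of one evaluation run.

    The defaults are the configuration found to perform best in the
    study this toolkit reproduces: discrete-Meyer basis, level-3 tree,
    400-sample windows, 30 principal components, KNN.
    """

    basis: str = "dmey"
    level: int = 3
    window: int = 400
    overlap: float = 0.0
    k_pca: int = 30
    standardize: bool = False
    classifier: str = "knn"
    params: dict[str, Any] | None = None
    subject_mode: str = "per-subject"  # or "pooled"

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)


@dataclass
class ConfusionMatrix:
    counts: np.ndarray  # (n_classes, n_classes), rows = true
    classes: tuple[str, ...]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        n = len(self.classes)
        if self.counts.shape != (n, n):
            raise ValueError("counts must be square and match classes")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def overall_accuracy(self) -> float:
        return float(np.trace(self.counts)) / self.total

    @classmethod
    def from_predictions(cls, y_true, y_pred, classes) -> "ConfusionMatrix":
        classes = tuple(classes)
        index = {c: i for i, c in enumerate(classes)}
        counts = np.zeros((len(classes), len(classes)), dtype=int)
        for t, p in zip(y_true, y_pred):
            counts[index[t], index[p]] += 1
        return cls(counts=counts, classes=classes)


def metrics_from_confusion(cm: ConfusionMatrix) -> pd.DataFrame:
    """Per-class one-vs-rest accuracy/recall/precision/F1 table."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    rows = []
    total = cm.total
    for i, cls_name in enumerate(cm.classes):
        tp = cm.counts[i, i]
        fn = cm.counts[i].sum() - tp
        fp = cm.counts[:, i].sum() - tp
        tn = total - tp - fn - fp
        if tp + fn == 0:
            warnings.warn(f"class {cls_name} absent from the evaluated windows", stacklevel=2)
        recall = tp / (tp + fn) if tp + fn else 0.0
        precision = tp / (tp + fp) if tp + fp else 0.0
        f1 = (
            2 * recall * precision / (recall + precision)
            if recall + precision > 0
            else 0.0
        )
        rows.append(
            {
                "class": cls_name,
                "accuracy": (tp + tn) / total,
                "recall": recall,
                "precision": precision,
                "f1": f1,
            }
        )
    return pd.DataFrame(rows).set_index("class")


@dataclass
class EvaluationReport:
    confusion: ConfusionMatrix
    per_class: pd.DataFrame
    overall_accuracy: float
    fold_accuracies: list[float]
    fold_assignments: dict[str, int]  # "subject/trial" -> fold
    config: dict[str, Any]
    seed: int

    @property
    def mean_fold_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))

    @property
    def std_fold_accuracy(self) -> float:
        return float(np.std(self.fold_accuracies))

    def to_json(self, path) -> None:
        obj = {
            "classes": list(self.confusion.classes),
            "confusion": self.confusion.counts.tolist(),
            "per_class": self.per_class.reset_index().to_dict(orient="records"),
            "overall_accuracy": self.overall_accuracy,
            "fold_accuracies": self.fold_accuracies,
            "fold_assignments": self.fold_assignments,
            "config": self.config,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=2)


def _stratified_trial_folds(
    labels_by_group: dict[tuple[str, int], str], n_folds: int, rng: np.random.Generator
) -> dict[tuple[str, int], int]:
    """Assign whole trials to folds, stratified by class."""
    by_class: dict[str, list[tuple[str, int]]] = {}
    for group, label in sorted(labels_by_group.items()):
        by_class.setdefault(label, []).append(group)
    assignment: dict[tuple[str, int], int] = {}
    for label in sorted(by_class):
        groups = by_class[label]
        if len(groups) < n_folds:
            raise ValueError(
                f"class {label} has {len(groups)} trials, fewer than {n_folds} folds"
            )
        order = rng.permutation(len(groups))
        for pos, gi in enumerate(order):
            assignment[groups[gi]] = pos % n_folds
    return assignment


def _evaluate_subject_set(
    recordings: list[Recording],
    config: PipelineConfig,
    n_folds: int,
    rng: np.random.Generator,
    classes: tuple[str, ...],
    perturb: Callable[[Window, np.random.Generator], Window] | None,
):
    # group key = one source recording (trial): all its windows share a fold
    windows: list[Window] = []
    gids: list[int] = []
    for gid, rec in enumerate(recordings):
        ws = segment(rec, config.window, config.overlap)
        windows.extend(ws)
        gids.extend([gid] * len(ws))
    fm = build_feature_matrix(windows, basis=config.basis, level=config.level)
    labels_by_group = {gid: rec.label for gid, rec in enumerate(recordings)}
    assignment = _stratified_trial_folds(labels_by_group, n_folds, rng)
    fold_of_row = np.array([assignment[g] for g in gids])

    counts = np.zeros((len(classes), len(classes)), dtype=int)
    fold_accs: list[float] = []
    for fold in range(n_folds):
        test_mask = fold_of_row == fold
        train_mask = ~test_mask
        Xtr, ytr = fm.values[train_mask], fm.labels[train_mask]
        k = min(config.k_pca, Xtr.shape[0] - 1, Xtr.shape[1])
        pca = pca_fit(Xtr, k=k, standardize=config.standardize)
        clf_seed = int(rng.integers(2**31))
        # PCA scores share one unit system (they are projections of the
        # same centred data), so the classifier-side z-scoring meant for
        # raw mixed-unit features is disabled here unless asked for
        params = {"scale": False, **(config.params or {})}
        model = classify.train(
            config.classifier,
            pca_transform(pca, Xtr),
            ytr,
            params=params,
            seed=clf_seed,
        )
        if perturb is None:
            Xte = fm.values[test_mask]
        else:
            test_windows = [windows[i] for i in np.flatnonzero(test_mask)]
            Xte = np.array([
                extract_features(perturb(w, rng), basis=config.basis, level=config.level)
                for w in test_windows
            ])
        yte = fm.labels[test_mask]
        pred = classify.predict(model, pca_transform(pca, Xte))
        fold_cm = ConfusionMatrix.from_predictions(yte, pred, classes)
        counts += fold_cm.counts
        fold_accs.append(fold_cm.overall_accuracy)
    str_assignment = {
        f"{rec.subject}/{rec.label}/{rec.trial}": assignment[gid]
        for gid, rec in enumerate(recordings)
    }
    return counts, fold_accs, str_assignment


def cross_validate(
    recordings: list[Recording],
    config: PipelineConfig | None = None,
    n_folds: int = 5,
    seed: int = 42,
    perturb: Callable[[Window, np.random.Generator], Window] | None = None,
) -> EvaluationReport:
    """Stratified, trial-grouped k-fold evaluation of the full pipeline.

    ``perturb``, if given, is applied to every *test* window before its
    features are extracted (the training fold always sees clean data);
    this is how the noise-robustness sweep injects disturbances.
    """
    config = config or PipelineConfig()
    if not recordings:
        raise ValueError("no recordings given")
    classes = tuple(sorted({rec.label for rec in recordings}))
    rng = np.random.default_rng(seed)

    if config.subject_mode == "per-subject":
        subject_sets = {}
        for rec in recordings:
            subject_sets.setdefault(rec.subject, []).append(rec)
        sets = [subject_sets[s] for s in sorted(subject_sets)]
    elif config.subject_mode == "pooled":
        sets = [recordings]
    else:
        raise ValueError(f"unknown subject_mode {config.subject_mode!r}")

    counts = np.zeros((len(classes), len(classes)), dtype=int)
    fold_accs: list[float] = []
    assignments: dict[str, int] = {}
    for subject_recs in sets:
        c, fa, assign = _evaluate_subject_set(
            subject_recs, config, n_folds, rng, classes, perturb
        )
        counts += c
        fold_accs.extend(fa)
        assignments.update(assign)
    cm = ConfusionMatrix(counts=counts, classes=classes)
    return EvaluationReport(
        confusion=cm,
        per_class=metrics_from_confusion(cm),
        overall_accuracy=cm.overall_accuracy,
        fold_accuracies=fold_accs,
        fold_assignments=assignments,
        config=config.to_dict(),
        seed=seed,
    )


def _sweep(recordings, config, values, make_config, n_folds, seed, classifiers,
           perturb_for=None) -> pd.DataFrame:
    table = {}
    for clf in classifiers:
        row = {}
        for v in values:
            cfg = make_config(config, v, clf)
            perturb = perturb_for(v) if perturb_for is not None else None
            report = cross_validate(recordings, cfg, n_folds=n_folds, seed=seed,
                                    perturb=perturb)
            row[v] = report.overall_accuracy
        table[clf] = row
    df = pd.DataFrame(table).T  # classifiers as rows, sweep values as columns
    df.index.name = "classifier"
    return df


def _with(config: PipelineConfig, **kw) -> PipelineConfig:
    d = config.to_dict()
    d.update(kw)
    return PipelineConfig(**d)


def sweep_basis(
    recordings, config: PipelineConfig | None = None,
    bases=DEFAULT_BASES, classifiers=DEFAULT_CLASSIFIERS,
    n_folds: int = 5, seed: int = 42,
) -> pd.DataFrame:
    """Accuracy per (wavelet basis, classifier)."""
    config = config or PipelineConfig()
    return _sweep(recordings, config, tuple(bases),
                  lambda c, v, clf: _with(c, basis=v, classifier=clf),
                  n_folds, seed, classifiers)


def sweep_dimension(
    recordings, config: PipelineConfig | None = None,
    dims=DEFAULT_DIMS, classifiers=DEFAULT_CLASSIFIERS,
    n_folds: int = 5, seed: int = 42,
) -> pd.DataFrame:
    """Accuracy per (retained PCA dimension, classifier)."""
    config = config or PipelineConfig()
    n_feat = 4 * 2 ** config.level * recordings[0].n_channels
    for d in dims:
        if d > n_feat:
            raise ValueError(f"PCA dimension {d} exceeds feature count {n_feat}")
    return _sweep(recordings, config, tuple(dims),
                  lambda c, v, clf: _with(c, k_pca=v, classifier=clf),
                  n_folds, seed, classifiers)


def sweep_noise(
    recordings, config: PipelineConfig | None = None,
    levels=DEFAULT_NOISE_LEVELS, reference_magnitude: float = 1.0,
    classifiers=DEFAULT_CLASSIFIERS, n_folds: int = 5, seed: int = 42,
) -> pd.DataFrame:
    """Train-clean / test-noisy accuracy per (noise level, classifier).

    Zero-mean Gaussian noise with standard deviation
    ``level * reference_magnitude`` is added to test windows only; their
    features are re-extracted from the perturbed samples.  With the
    default ``reference_magnitude = 1`` the levels are absolute signal
    units, meaningful for raw data of magnitude ~1e-2.
    """
    config = config or PipelineConfig()
    for lv in levels:
        if lv <= 0:
            raise ValueError("noise levels must be positive")

    def perturb_for(level):
        std = level * reference_magnitude

        def perturb(w: Window, rng: np.random.Generator) -> Window:
            noisy = w.samples + std * rng.standard_normal(w.samples.shape)
            return Window(samples=noisy, label=w.label, subject=w.subject,
                          trial=w.trial, start_index=w.start_index, rate=w.rate)

        return perturb

    return _sweep(recordings, config, tuple(levels),
                  lambda c, v, clf: _with(c, classifier=clf),
                  n_folds, seed, classifiers, perturb_for=perturb_for)


def sweep_window(
    recordings, config: PipelineConfig | None = None,
    sizes=DEFAULT_WINDOW_SIZES, classifiers=DEFAULT_CLASSIFIERS,
    n_folds: int = 5, seed: int = 42,
) -> pd.DataFrame:
    """Accuracy per (window length in samples, classifier)."""
    config = config or PipelineConfig()
    min_len = min(rec.n_samples for rec in recordings)
    for sz in sizes:
        if sz > min_len:
            raise ValueError(f"window size {sz} exceeds shortest trial ({min_len})")
    return _sweep(recordings, config, tuple(sizes),
                  lambda c, v, clf: _with(c, window=v, classifier=clf),
                  n_folds, seed, classifiers)


def kruskal_wallis_screen(X: np.ndarray, labels) -> pd.DataFrame:
    """Kruskal–Wallis H and p per feature column across the label groups.

    Uses the rank-based H statistic with midrank tie correction and the
    chi-squared approximation with (k - 1) degrees of freedom.  Constant
    columns yield H = 0, p = 1 with a warning.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    labels = np.asarray(labels)
    ulabels = np.unique(labels)
    if ulabels.size < 2:
        raise ValueError("need at least two label groups")
    for lab in ulabels:
        if np.sum(labels == lab) < 2:
            raise ValueError(f"group {lab} has fewer than 2 rows")
    rows = []
    for j in range(X.shape[1]):
        groups = [X[labels == lab, j] for lab in ulabels]
        if np.ptp(X[:, j]) == 0:
            warnings.warn(f"feature column {j} is constant; H=0, p=1", stacklevel=2)
            h, p = 0.0, 1.0
        else:
            h, p = scipy.stats.kruskal(*groups)
        rows.append({"feature": j, "H": float(h), "p": float(p)})
    return pd.DataFrame(rows).set_index("feature")
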