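"""Splits, metrics, cross-validation, and single-classifier baselines.

The metric suite is the standard multiclass one: a true x predicted
confusion matrix, overall accuracy (trace / total), and per-class plus
macro-averaged precision, recall and F1. Macro averages are unweighted class
means; with a balanced class design they coincide with sample-weighted
averages. A class that is never predicted gets precision 0 and is flagged in
the report.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.metrics import confusion_matrix, precision_recall_fscore_support
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline

from .dataset import SpectralDataset
from .models import make_classifier


@dataclass
class EvaluationReport:
    """Confusion matrix and the derived classification metrics."""

    class_order: np.ndarray
    confusion: np.ndarray  # true class x predicted class counts
    accuracy: float
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    never_predicted: list = field(default_factory=list)

    @property
    def macro_precision(self) -> float:
        return float(self.precision.mean())

    @property
    def macro_recall(self) -> float:
        return float(self.recall.mean())

    @property
    def macro_f1(self) -> float:
        return float(self.f1.mean())

    def confusion_frame(self) -> pd.DataFrame:
        """Confusion matrix with margins: per-class precision as the last
        row, per-class recall as the last column, overall accuracy in the
        corner cell."""
        classes = [str(c) for c in self.class_order]
        frame = pd.DataFrame(
            self.confusion.astype(float), index=classes, columns=classes
        )
        frame["recall"] = self.recall
        bottom = pd.Series(
            np.append(self.precision, self.accuracy), index=frame.columns
        )
        frame.loc["precision"] = bottom
        return frame

    def to_dict(self) -> dict:
        return {
            "class_order": [str(c) for c in self.class_order],
            "confusion": self.confusion.tolist(),
            "accuracy": self.accuracy,
            "precision": self.precision.tolist(),
            "recall": self.recall.tolist(),
            "f1": self.f1.tolist(),
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
            "never_predicted": [str(c) for c in self.never_predicted],
        }


def compute_report(truth, predictions, class_order=None) -> EvaluationReport:
    """Build an :class:`EvaluationReport`; macro averages run over the
    classes present in ``truth``."""
    truth = np.asarray(truth)
    predictions = np.asarray(predictions)
    if truth.shape != predictions.shape:
        raise ValueError("truth and predictions must have equal length")
    if class_order is None:
        class_order = np.unique(truth)
    else:
        class_order = np.asarray(class_order)
        unknown = set(predictions) - set(class_order)
        if unknown:
            raise ValueError(f"predicted label(s) outside class_order: {sorted(map(str, unknown))}")
        if set(truth) - set(class_order):
            raise ValueError("truth contains labels outside class_order")
    present = np.isin(class_order, np.unique(truth))
    cm = confusion_matrix(truth, predictions, labels=class_order)
    p, r, f, _ = precision_recall_fscore_support(
        truth, predictions, labels=class_order, zero_division=0
    )
    never = [c for c in class_order[cm.sum(axis=0) == 0]]
    return EvaluationReport(
        class_order=class_order[present],
        confusion=cm[np.ix_(present, present)],
        accuracy=float(np.trace(cm) / cm.sum()),
        precision=p[present],
        recall=r[present],
        f1=f[present],
        never_predicted=never,
    )


def split_dataset(
    dataset: SpectralDataset,
    proportions: tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 0,
) -> SpectralDataset:
    """Stratified train/validation/test tagging at the given proportions.

    Within each class, counts are apportioned by largest remainder so they
    sum exactly; assignment is a seeded shuffle. Every class must supply at
    least one sample to each split with a nonzero proportion.
    """
    proportions = np.asarray(proportions, dtype=float)
    if proportions.shape != (3,) or np.any(proportions < 0):
        raise ValueError("proportions must be three non-negative numbers")
    if abs(proportions.sum() - 1.0) > 1e-9:
        raise ValueError("proportions must sum to 1")
    rng = np.random.default_rng(seed)
    tags = np.empty(dataset.n_spectra, dtype=object)
    for cls in dataset.classes:
        idx = np.flatnonzero(dataset.labels == cls)
        n = idx.size
        base = proportions * n
        counts = np.floor(base).astype(int)
        remainder = base - counts
        for j in np.argsort(-remainder)[: n - counts.sum()]:
            counts[j] += 1
        if np.any((counts == 0) & (proportions > 0)):
            raise ValueError(
                f"class {str(cls)!r} has too few samples ({n}) to stratify at "
                f"proportions {tuple(float(p) for p in proportions)}"
            )
        idx = rng.permutation(idx)
        bounds = np.cumsum(counts)
        tags[idx[: bounds[0]]] = "train"
        tags[idx[bounds[0] : bounds[1]]] = "validation"
        tags[idx[bounds[1] :]] = "test"
    out = dataset.subset(np.arange(dataset.n_spectra))
    out.split = tags
    return out


def cross_validate(
    dataset: SpectralDataset,
    classifier_spec,
    folds: int = 5,
    seed: int = 0,
) -> dict:
    """Stratified k-fold cross-validation of one classifier.

    Returns per-fold :class:`EvaluationReport` objects plus the mean and sd
    of accuracy and macro precision/recall/F1 across folds.
    """
    if folds < 2:
        raise ValueError("folds must be at least 2")
    smallest = min(np.sum(dataset.labels == c) for c in dataset.classes)
    if folds > smallest:
        raise ValueError(
            f"folds ({folds}) exceed the smallest class count ({smallest})"
        )
    X, y = dataset.intensities, dataset.labels
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    reports = []
    for tr, te in skf.split(X, y):
        clf = make_classifier(classifier_spec, random_state=seed)
        clf.fit(X[tr], y[tr])
        reports.append(compute_report(y[te], clf.predict(X[te])))
    def agg(fn):
        vals = np.array([fn(r) for r in reports])
        return {"mean": float(vals.mean()), "sd": float(vals.std(ddof=0))}
    return {
        "reports": reports,
        "accuracy": agg(lambda r: r.accuracy),
        "macro_precision": agg(lambda r: r.macro_precision),
        "macro_recall": agg(lambda r: r.macro_recall),
        "macro_f1": agg(lambda r: r.macro_f1),
    }


def baseline_suite(
    dataset: SpectralDataset,
    with_pca: bool = False,
    pca_variance: float = 0.95,
    random_state: int | None = 0,
    eval_split: str = "test",
) -> dict[str, EvaluationReport]:
    """Fit the three single classifiers — optionally behind a PCA projection
    retaining ``pca_variance`` of the training variance — on the train split
    and report on ``eval_split``.

    PCA is fitted on the training split only; no evaluation-split
    information reaches any fitted transform. Returns 3 reports, or 6 with
    PCA variants.
    """
    train = dataset.split_part("train")
    test = dataset.split_part(eval_split)
    out: dict[str, EvaluationReport] = {}
    for name in ("svm", "rf", "knn"):
        clf = make_classifier(name, random_state=random_state)
        clf.fit(train.intensities, train.labels)
        out[name] = compute_report(
            test.labels, clf.predict(test.intensities), class_order=dataset.classes
        )
    if with_pca:
        for name in ("svm", "rf", "knn"):
            clf = make_pipeline(
                PCA(n_components=pca_variance, random_state=random_state),
                make_classifier(name, random_state=random_state),
            )
            clf.fit(train.intensities, train.labels)
            out[f"pca_{name}"] = compute_report(
                test.labels, clf.predict(test.intensities), class_order=dataset.classes
            )
    return out


def summary_table(reports: dict[str, EvaluationReport]) -> pd.DataFrame:
    """Accuracy / macro recall / macro precision / macro F1, one column per
    model."""
    return pd.DataFrame(
        {
            name: {
                "accuracy": r.accuracy,
                "recall": r.macro_recall,
                "precision": r.macro_precision,
                "f1": r.macro_f1,
            }
            for name, r in reports.items()
        }
    )
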