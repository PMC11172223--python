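"""Precision x recall weighted fusion of constituent classifiers.

Each sub-model i is pre-trained independently, its per-class precision P_i
and recall R_i are measured on a weight-estimation split, and its vote for
class c carries weight

    W[i, c] = P_i[c] * R_i[c]        (no normalization).

At prediction time sub-model outputs Z_i are one-hot hard-label indicators
and the fused score of class c is sum_i W[i, c] * Z_i[c]; the argmax class
wins. Exact score ties are resolved by the prediction of the sub-model with
the highest macro-F1 on the weight split. A soft mode (Z_i = predicted
probability vector) exists behind ``score_mode="soft"``; the hard-label mode
is canonical.

The default sub-model trio is a scaled RBF-kernel SVM, a random forest, and
scaled 5-nearest-neighbours. "Parallel pre-training" is a throughput notion
only: sub-models are trained independently, so results never depend on
training order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.metrics import f1_score, precision_recall_fscore_support
from sklearn.model_selection import train_test_split
from sklearn.utils.validation import check_is_fitted

from .models import make_classifier

_TIE_TOL = 1e-12


class ConfigurationError(ValueError):
    """Raised for inconsistent fusion inputs (e.g. a class absent from the
    weight split)."""


@dataclass
class ClassMetrics:
    """Per-class precision/recall of one sub-model on the weight split."""

    source: str
    classes: np.ndarray
    precision: np.ndarray
    recall: np.ndarray

    def __post_init__(self) -> None:
        self.classes = np.asarray(self.classes)
        self.precision = np.asarray(self.precision, dtype=float)
        self.recall = np.asarray(self.recall, dtype=float)
        for arr, name in ((self.precision, "precision"), (self.recall, "recall")):
            if arr.shape != self.classes.shape:
                raise ConfigurationError(f"one {name} value per class is required")
            if np.any((arr < 0) | (arr > 1)):
                raise ConfigurationError(f"{name} values must lie in [0, 1]")


@dataclass
class FusionWeights:
    """Sub-model x class weight matrix W[i, c] = P_i[c] * R_i[c]."""

    classes: np.ndarray
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != len(self.classes):
            raise ConfigurationError("weight matrix must be n_submodels x n_classes")


def compute_weights(metrics: list[ClassMetrics]) -> FusionWeights:
    """Elementwise W[i, c] = P_i[c] * R_i[c]; all metrics must share one
    class set."""
    if not metrics:
        raise ConfigurationError("at least one sub-model's metrics are required")
    classes = metrics[0].classes
    for m in metrics[1:]:
        if not np.array_equal(m.classes, classes):
            raise ConfigurationError(
                f"class-set mismatch between sub-models "
                f"{metrics[0].source!r} and {m.source!r}"
            )
    matrix = np.stack([m.precision * m.recall for m in metrics])
    return FusionWeights(classes=classes, matrix=matrix)


def pretrain(
    submodels: list[tuple[str, BaseEstimator]],
    X_train,
    y_train,
    X_weight,
    y_weight,
) -> tuple[list[tuple[str, BaseEstimator]], list[ClassMetrics]]:
    """Fit each sub-model on the training split and measure its per-class
    precision/recall on the weight split.

    Sub-models are fitted independently (results are order-invariant). A
    class never predicted gets precision 0; a class absent from the weight
    split makes recall undefined and raises ConfigurationError naming it.
    """
    y_train = np.asarray(y_train)
    y_weight = np.asarray(y_weight)
    if len(y_train) == 0 or len(y_weight) == 0:
        raise ConfigurationError("train and weight splits must be non-empty")
    classes = np.unique(y_train)
    missing = set(classes) - set(np.unique(y_weight))
    if missing:
        raise ConfigurationError(
            f"class(es) {sorted(map(str, missing))} absent from the weight split; "
            "their recall is undefined"
        )
    fitted, metrics = [], []
    for name, est in submodels:
        est = clone(est).fit(X_train, y_train)
        pred = est.predict(X_weight)
        p, r, _, _ = precision_recall_fscore_support(
            y_weight, pred, labels=classes, zero_division=0
        )
        fitted.append((name, est))
        metrics.append(ClassMetrics(source=name, classes=classes, precision=p, recall=r))
    return fitted, metrics


def default_submodels(random_state: int | None = None):
    return [(name, make_classifier(name, random_state)) for name in ("svm", "rf", "knn")]


class FusionClassifier(ClassifierMixin, BaseEstimator):
    """Weighted-vote ensemble with per-class precision x recall weights.

    Parameters
    ----------
    submodels : list of (name, estimator) or None
        Constituent classifiers; None gives the scaled-SVM / random-forest /
        scaled-KNN trio.
    weight_mode : {"holdout", "train"}
        Where P_i, R_i are measured when no explicit weight split is passed
        to :meth:`fit`: a stratified holdout carved from the training data
        (default), or the training data itself (training-set metrics of a
        forest are degenerately ~1, collapsing the weights toward uniform).
    holdout_frac : float
        Fraction held out in "holdout" mode.
    score_mode : {"hard", "soft"}
        Sub-model output encoding Z_i: one-hot predicted label (canonical) or
        predicted class probabilities.
    random_state : int or None
        Seeds the internal holdout and any stochastic sub-model.

    Attributes
    ----------
    classes_ : class labels in weight-matrix column order
    submodels_ : fitted (name, estimator) pairs
    class_metrics_ : per-sub-model :class:`ClassMetrics`
    weights_ : :class:`FusionWeights`
    tie_breaker_ : index of the sub-model resolving score ties
    """

    def __init__(
        self,
        submodels=None,
        weight_mode: str = "holdout",
        holdout_frac: float = 0.25,
        score_mode: str = "hard",
        random_state: int | None = None,
    ):
        self.submodels = submodels
        self.weight_mode = weight_mode
        self.holdout_frac = holdout_frac
        self.score_mode = score_mode
        self.random_state = random_state

    # -------------------------------------------------------------- fitting

    def fit(self, X, y, X_weight=None, y_weight=None):
        """Fit sub-models on (X, y); measure weights on (X_weight, y_weight)
        when given, else per ``weight_mode``."""
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if self.weight_mode not in ("holdout", "train"):
            raise ValueError("weight_mode must be 'holdout' or 'train'")
        if self.score_mode not in ("hard", "soft"):
            raise ValueError("score_mode must be 'hard' or 'soft'")
        submodels = (
            default_submodels(self.random_state)
            if self.submodels is None
            else [(n, e) for n, e in self.submodels]
        )
        if not submodels:
            raise ConfigurationError("at least one sub-model is required")

        if X_weight is None:
            if self.weight_mode == "train":
                X_fit, y_fit, X_weight, y_weight = X, y, X, y
            else:
                X_fit, X_weight, y_fit, y_weight = train_test_split(
                    X,
                    y,
                    test_size=self.holdout_frac,
                    stratify=y,
                    random_state=self.random_state,
                )
        else:
            X_fit, y_fit = X, y
            X_weight = np.asarray(X_weight, dtype=float)
            y_weight = np.asarray(y_weight)

        self.submodels_, self.class_metrics_ = pretrain(
            submodels, X_fit, y_fit, X_weight, y_weight
        )
        self.weights_ = compute_weights(self.class_metrics_)
        self.classes_ = self.weights_.classes
        macro_f1 = [
            f1_score(y_weight, est.predict(X_weight), average="macro", zero_division=0)
            for _, est in self.submodels_
        ]
        self.submodel_macro_f1_ = np.asarray(macro_f1)
        self.tie_breaker_ = int(np.argmax(self.submodel_macro_f1_))
        self.n_features_in_ = X.shape[1]
        return self

    # ----------------------------------------------------------- prediction

    def _submodel_outputs(self, X) -> np.ndarray:
        """Z, shape (n_submodels, n_samples, n_classes)."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} features, got {X.shape[1:]}"
            )
        class_pos = {c: j for j, c in enumerate(self.classes_)}
        Z = np.zeros((len(self.submodels_), X.shape[0], len(self.classes_)))
        for i, (_, est) in enumerate(self.submodels_):
            if self.score_mode == "soft":
                proba = est.predict_proba(X)
                cols = [class_pos[c] for c in est.classes_]
                Z[i][:, cols] = proba
            else:
                pred = est.predict(X)
                Z[i, np.arange(X.shape[0]), [class_pos[c] for c in pred]] = 1.0
        return Z

    def decision_scores(self, X) -> np.ndarray:
        """Fused per-class scores sum_i W[i, c] Z_i[c], shape
        (n_samples, n_classes)."""
        check_is_fitted(self)
        Z = self._submodel_outputs(X)
        return np.einsum("ic,inc->nc", self.weights_.matrix, Z)

    def predict(self, X):
        check_is_fitted(self)
        X = np.asarray(X, dtype=float)
        scores = self.decision_scores(X)
        winners = self.classes_[np.argmax(scores, axis=1)]
        tied = (scores >= scores.max(axis=1, keepdims=True) - _TIE_TOL).sum(axis=1) > 1
        if np.any(tied):
            ref = self.submodels_[self.tie_breaker_][1].predict(X[tied])
            for out_i, row_scores, ref_pred in zip(
                np.flatnonzero(tied), scores[tied], ref
            ):
                tied_classes = self.classes_[
                    row_scores >= row_scores.max() - _TIE_TOL
                ]
                winners[out_i] = (
                    ref_pred if ref_pred in tied_classes else tied_classes[0]
                )
        return winners


def fuse_predict(X, model: FusionClassifier):
    """Fused class predictions plus the per-class fused score matrix."""
    return model.predict(X), model.decision_scores(X)


def tune_submodels(
    X_train,
    y_train,
    X_val,
    y_val,
    names: tuple[str, ...] = ("svm", "rf", "knn"),
    random_state: int | None = None,
):
    """Pick each sub-model's hyperparameters from its small documented grid
    by validation accuracy (ties keep the first grid entry); returns
    (name, unfitted estimator) pairs for :class:`FusionClassifier`."""
    from .models import PARAM_GRIDS, set_model_params

    y_val = np.asarray(y_val)
    chosen = []
    for name in names:
        base = make_classifier(name, random_state)
        best_acc, best_est = -1.0, None
        for params in PARAM_GRIDS[name]:
            est = set_model_params(base, params).fit(X_train, y_train)
            acc = float(np.mean(est.predict(X_val) == y_val))
            if acc > best_acc:
                best_acc, best_est = acc, set_model_params(base, params)
        chosen.append((name, best_est))
    return chosen
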