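"""Stacked relevance/redundancy channel selection.

Stage one ranks every spectral channel by a normalized mutual-information
coefficient against the class label,

    MIC(X, Y) = I(X; Y) / sqrt(H(X) * H(Y)),

with the channel intensities discretized into equal-frequency (quantile)
bins. The sqrt-of-product normalization bounds the score to [0, 1]: 1 for a
deterministic one-to-one relationship, 0 for independence. Stage two prunes
redundancy among the top-k ranked channels: a greedy pass in descending
score order keeps a channel only if its absolute Spearman rank correlation
with every already-kept channel stays at or below a threshold tau. Adjacent
channels sampling the same emission line are near-perfectly rank-correlated,
so this collapses each line to its most label-relevant channel(s).

Both stage parameters (k and tau) are tuned by validation-accuracy grid
search.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin, clone
from sklearn.utils.validation import check_is_fitted

from .dataset import SpectralDataset
from .models import make_classifier

#: Correlation-strength bands for reporting; conventional cutoffs, configurable.
DEFAULT_CATEGORY_THRESHOLDS = {"strong": 0.6, "moderately_strong": 0.4, "weak": 0.2}
CATEGORY_ORDER = ("strong", "moderately_strong", "weak", "extremely_weak")


# ---------------------------------------------------------------- primitives


def entropy(values) -> float:
    """Shannon entropy in bits of the empirical distribution of a discrete
    vector."""
    values = np.asarray(values)
    if values.size == 0:
        raise ValueError("entropy of an empty vector is undefined")
    _, counts = np.unique(values, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def discretize(x, bins: int) -> np.ndarray:
    """Equal-frequency discretization into at most ``bins`` bins.

    Bin edges are the interior quantiles of x; ties always land in the same
    bin, so heavily tied data may occupy fewer than ``bins`` bins.
    """
    x = np.asarray(x, dtype=float)
    if bins < 1:
        raise ValueError("bins must be positive")
    edges = np.quantile(x, np.arange(1, bins) / bins)
    return np.searchsorted(edges, x, side="right")


def default_bins(n: int) -> int:
    """min(16, ceil(sqrt(n))) — keeps expected cell counts workable."""
    return min(16, math.ceil(math.sqrt(n)))


def mutual_information(x_disc, y) -> float:
    """I(X; Y) in bits from the joint empirical distribution of two discrete
    vectors."""
    x_codes = np.unique(x_disc, return_inverse=True)[1]
    y_codes = np.unique(y, return_inverse=True)[1]
    nx, ny = x_codes.max() + 1, y_codes.max() + 1
    joint = np.bincount(x_codes * ny + y_codes, minlength=nx * ny).reshape(nx, ny)
    joint = joint / joint.sum()
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    return float((joint[nz] * np.log2(joint[nz] / (px @ py)[nz])).sum())


def mic_score(
    channel,
    labels,
    bins: int | None = None,
    denominator: str = "sqrt",
) -> float:
    """Normalized mutual information between one channel and the class label.

    The channel is quantile-discretized into <= ``bins`` bins
    (default ``min(16, ceil(sqrt(n)))``); the score is
    I(X;Y)/sqrt(H(X) H(Y)) clipped to [0, 1], or 0 when either marginal
    entropy vanishes. ``denominator="product"`` divides by H(X)·H(Y) instead.
    """
    channel = np.asarray(channel, dtype=float)
    labels = np.asarray(labels)
    if channel.shape != labels.shape or channel.ndim != 1:
        raise ValueError("channel and labels must be equal-length vectors")
    if channel.size < 2:
        raise ValueError("at least two samples are required")
    if np.unique(labels).size < 2:
        raise ValueError("labels must contain at least two classes")
    if denominator not in ("sqrt", "product"):
        raise ValueError("denominator must be 'sqrt' or 'product'")
    if bins is None:
        bins = default_bins(channel.size)
    x = discretize(channel, bins)
    hx, hy = entropy(x), entropy(labels)
    if hx == 0.0 or hy == 0.0:
        return 0.0
    denom = math.sqrt(hx * hy) if denominator == "sqrt" else hx * hy
    return float(np.clip(mutual_information(x, labels) / denom, 0.0, 1.0))


def spearman(x, y) -> float:
    """Spearman rank correlation (Pearson on average ranks, tie-robust).

    With no ties this equals the closed form 1 - 6 sum(d_i^2) / (n (n^2-1))
    on rank differences d_i. A constant input has no rank ordering; the
    result is returned as 0.0 with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be equal-length vectors")
    if x.size < 3:
        raise ValueError("at least three samples are required")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn(
            "Spearman correlation undefined for a constant vector; returning 0.0",
            RuntimeWarning,
            stacklevel=2,
        )
        return 0.0
    return float(stats.spearmanr(x, y).statistic)


def _rank_transform(X: np.ndarray) -> np.ndarray:
    """Column-wise average ranks, standardized; constant columns become 0."""
    ranks = stats.rankdata(X, axis=0)
    ranks -= ranks.mean(axis=0)
    norm = np.sqrt((ranks**2).sum(axis=0))
    norm[norm == 0] = 1.0
    return ranks / norm


def spearman_matrix(X: np.ndarray) -> np.ndarray:
    """Pairwise Spearman correlations of the columns of X (constant columns
    correlate 0 with everything)."""
    r = _rank_transform(np.asarray(X, dtype=float))
    return r.T @ r


# ---------------------------------------------------------------- containers


@dataclass
class SelectionResult:
    """Outcome of ranking and (optionally) pruning channels.

    ``selected`` is ordered by descending score and always a subset of the
    first ``top_k`` entries of ``rank_order``; after pruning no selected pair
    has absolute Spearman correlation above ``spearman_threshold``.
    """

    mic_scores: np.ndarray
    rank_order: np.ndarray
    category: np.ndarray
    top_k: int
    selected: np.ndarray
    spearman_threshold: float | None = None
    category_thresholds: dict = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_THRESHOLDS)
    )

    def category_counts(self) -> dict[str, int]:
        return {c: int((self.category == c).sum()) for c in CATEGORY_ORDER}

    def to_dict(self) -> dict:
        return {
            "mic_scores": self.mic_scores.tolist(),
            "rank_order": self.rank_order.tolist(),
            "category": self.category.tolist(),
            "top_k": int(self.top_k),
            "spearman_threshold": self.spearman_threshold,
            "selected": self.selected.tolist(),
            "category_thresholds": self.category_thresholds,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SelectionResult":
        return cls(
            mic_scores=np.asarray(d["mic_scores"], dtype=float),
            rank_order=np.asarray(d["rank_order"], dtype=int),
            category=np.asarray(d["category"], dtype=object),
            top_k=int(d["top_k"]),
            selected=np.asarray(d["selected"], dtype=int),
            spearman_threshold=d.get("spearman_threshold"),
            category_thresholds=d.get(
                "category_thresholds", dict(DEFAULT_CATEGORY_THRESHOLDS)
            ),
        )


def categorize(scores: np.ndarray, thresholds: dict | None = None) -> np.ndarray:
    """Map scores to the four correlation-strength bands."""
    t = dict(DEFAULT_CATEGORY_THRESHOLDS) if thresholds is None else dict(thresholds)
    out = np.full(scores.shape, "extremely_weak", dtype=object)
    out[scores >= t["weak"]] = "weak"
    out[scores >= t["moderately_strong"]] = "moderately_strong"
    out[scores >= t["strong"]] = "strong"
    return out


# ---------------------------------------------------------------- estimator


class StackedFeatureSelector(TransformerMixin, BaseEstimator):
    """MIC ranking followed by Spearman redundancy pruning, as a transformer.

    Parameters
    ----------
    top_k : int or None
        Channels kept after the relevance stage (None keeps all).
    spearman_threshold : float in (0, 1] or None
        Redundancy threshold tau; None disables pruning.
    bins : int or None
        Quantile bins for MIC discretization (None: min(16, ceil(sqrt(n)))).
    denominator : "sqrt" or "product"
        Normalization of the mutual information.
    category_thresholds : dict or None
        Cutoffs for the strong / moderately strong / weak bands.

    Attributes
    ----------
    mic_scores_ : per-channel scores in [0, 1]
    rank_order_ : channel indices by descending score (ties: lower index first)
    selected_ : surviving channel indices, descending-score order
    result_ : the full :class:`SelectionResult`
    """

    def __init__(
        self,
        top_k: int | None = 300,
        spearman_threshold: float | None = 0.9,
        bins: int | None = None,
        denominator: str = "sqrt",
        category_thresholds: dict | None = None,
    ):
        self.top_k = top_k
        self.spearman_threshold = spearman_threshold
        self.bins = bins
        self.denominator = denominator
        self.category_thresholds = category_thresholds

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be 2-D with one label per row")
        if np.unique(y).size < 2:
            raise ValueError("selection requires at least two classes")
        tau = self.spearman_threshold
        if tau is not None and not 0.0 < tau <= 1.0:
            raise ValueError(f"spearman_threshold must be in (0, 1], got {tau}")

        n, n_channels = X.shape
        bins = default_bins(n) if self.bins is None else self.bins
        scores = np.array(
            [
                mic_score(X[:, j], y, bins=bins, denominator=self.denominator)
                for j in range(n_channels)
            ]
        )
        # stable mergesort on -scores: equal scores keep ascending channel index
        order = np.argsort(-scores, kind="stable")
        k = n_channels if self.top_k is None else min(self.top_k, n_channels)
        top = order[:k]
        if tau is not None:
            kept = _greedy_prune(X[:, top], tau)
            selected = top[kept]
        else:
            selected = top

        self.n_features_in_ = n_channels
        self.mic_scores_ = scores
        self.rank_order_ = order
        self.category_ = categorize(scores, self.category_thresholds)
        self.selected_ = selected
        self.result_ = SelectionResult(
            mic_scores=scores,
            rank_order=order,
            category=self.category_,
            top_k=k,
            selected=selected,
            spearman_threshold=tau,
            category_thresholds=dict(
                DEFAULT_CATEGORY_THRESHOLDS
                if self.category_thresholds is None
                else self.category_thresholds
            ),
        )
        return self

    def transform(self, X):
        check_is_fitted(self)
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("channel count changed between fit and transform")
        return X[:, self.selected_]

    def get_support(self, indices: bool = False):
        check_is_fitted(self)
        if indices:
            return self.selected_.copy()
        mask = np.zeros(self.n_features_in_, dtype=bool)
        mask[self.selected_] = True
        return mask


def _greedy_prune(X_top: np.ndarray, tau: float) -> np.ndarray:
    """Greedy redundancy filter over columns ordered by descending relevance.

    Keeps column j iff |rho(j, kept)| <= tau for every already-kept column;
    column 0 is always kept. A perfect monotone duplicate (|rho| = 1) is
    prunable at any tau, including tau = 1: it can never add information.
    Returns kept positions (ascending = descending relevance). The pairwise
    constraint holds by construction.
    """
    rho = np.abs(spearman_matrix(X_top))
    kept: list[int] = []
    for j in range(X_top.shape[1]):
        if all(rho[j, i] <= tau and rho[j, i] < 1.0 - 1e-12 for i in kept):
            kept.append(j)
    return np.array(kept, dtype=int)


# ------------------------------------------------------- functional wrappers


def rank_channels(
    dataset: SpectralDataset,
    bins: int | None = None,
    denominator: str = "sqrt",
    category_thresholds: dict | None = None,
) -> SelectionResult:
    """Score and rank every channel of a labelled dataset (no pruning)."""
    dataset.require_min_classes(2)
    sel = StackedFeatureSelector(
        top_k=None,
        spearman_threshold=None,
        bins=bins,
        denominator=denominator,
        category_thresholds=category_thresholds,
    ).fit(dataset.intensities, dataset.labels)
    return sel.result_


def prune_redundant(
    dataset: SpectralDataset, result: SelectionResult, tau: float
) -> SelectionResult:
    """Redundancy-prune the top-k channels of an existing ranking at
    threshold tau."""
    if not 0.0 < tau <= 1.0:
        raise ValueError(f"tau must be in (0, 1], got {tau}")
    top = result.rank_order[: result.top_k]
    kept = _greedy_prune(dataset.intensities[:, top], tau)
    return replace(result, selected=top[kept], spearman_threshold=tau)


# ------------------------------------------------------------- grid searches


@dataclass
class GridSearchResult:
    """Accuracy table over a selection-parameter grid plus the winner."""

    table: pd.DataFrame
    best: float | int

    def __iter__(self):  # allows `best_k, table = result`
        yield self.best
        yield self.table


def _fit_score(classifier_spec, X_tr, y_tr, X_val, y_val, random_state) -> float:
    clf = make_classifier(classifier_spec, random_state=random_state)
    clf.fit(X_tr, y_tr)
    return float(np.mean(clf.predict(X_val) == y_val))


def _split_xy(dataset: SpectralDataset):
    train, val = dataset.split_part("train"), dataset.split_part("validation")
    if train.n_spectra == 0 or val.n_spectra == 0:
        raise ValueError("grid search needs non-empty train and validation splits")
    return train, val


def grid_search_k(
    dataset: SpectralDataset,
    classifier_spec,
    k_min: int = 50,
    k_max: int = 5000,
    step: int = 50,
    bins: int | None = None,
    random_state: int | None = 0,
) -> GridSearchResult:
    """Validation-accuracy grid search over the relevance cutoff k.

    Channels are ranked once on the training split; for each k on the grid
    the classifier is refitted on the top-k channels and scored on the
    validation split. Ties go to the smallest k. A grid reaching past the
    channel count is truncated with a warning.
    """
    train, val = _split_xy(dataset)
    if k_max > dataset.n_channels:
        warnings.warn(
            f"k grid truncated to the {dataset.n_channels} available channels",
            RuntimeWarning,
            stacklevel=2,
        )
        k_max = dataset.n_channels
    ks = list(range(k_min, k_max + 1, step))
    if not ks:
        raise ValueError("empty k grid")
    ranking = rank_channels(train, bins=bins)
    rows = []
    for k in ks:
        idx = ranking.rank_order[:k]
        acc = _fit_score(
            classifier_spec,
            train.intensities[:, idx],
            train.labels,
            val.intensities[:, idx],
            val.labels,
            random_state,
        )
        rows.append({"k": k, "accuracy": acc})
    table = pd.DataFrame(rows)
    best_k = int(table.loc[table["accuracy"].idxmax(), "k"])  # idxmax: first max
    return GridSearchResult(table=table, best=best_k)


def grid_search_threshold(
    dataset: SpectralDataset,
    classifier_spec,
    k: int,
    tau_min: float = 0.80,
    tau_max: float = 0.99,
    step: float = 0.01,
    bins: int | None = None,
    random_state: int | None = 0,
) -> GridSearchResult:
    """Validation-accuracy grid search over the redundancy threshold tau.

    For each tau the top-k ranking is pruned, the classifier refitted on the
    survivors and scored on the validation split; the table also records the
    surviving feature count. Accuracy ties go to the tau with the fewest
    surviving features (then the smaller tau).
    """
    train, val = _split_xy(dataset)
    taus = np.round(np.arange(tau_min, tau_max + step / 2, step), 10)
    if taus.size == 0 or taus.min() <= 0 or taus.max() > 1:
        raise ValueError("tau grid must lie within (0, 1]")
    ranking = rank_channels(train, bins=bins)
    ranking = replace(ranking, top_k=min(k, dataset.n_channels))
    rows = []
    for tau in taus:
        pruned = prune_redundant(train, ranking, float(tau))
        idx = pruned.selected
        acc = _fit_score(
            classifier_spec,
            train.intensities[:, idx],
            train.labels,
            val.intensities[:, idx],
            val.labels,
            random_state,
        )
        rows.append({"tau": float(tau), "n_features": idx.size, "accuracy": acc})
    table = pd.DataFrame(rows)
    order = table.sort_values(
        ["accuracy", "n_features", "tau"], ascending=[False, True, True]
    )
    best_tau = float(order.iloc[0]["tau"])
    return GridSearchResult(table=table, best=best_tau)
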