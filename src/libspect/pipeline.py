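"""Three-stage composite: smoothing -> stacked selection -> weighted fusion.

:class:`SpectralPipeline` wires the Gaussian smoother, the MIC/Spearman
stacked selector and the precision x recall fusion classifier into one
estimator fitted from a split-tagged :class:`SpectralDataset`: sub-models
train on the train split, fusion weights and (optionally) the selection
grid searches use the validation split, and nothing sees the test split.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .dataset import SpectralDataset
from .fusion import FusionClassifier, tune_submodels
from .selection import (
    SelectionResult,
    StackedFeatureSelector,
    grid_search_k,
    grid_search_threshold,
)
from .smoothing import GaussianSmoother


class SpectralPipeline(ClassifierMixin, BaseEstimator):
    """End-to-end spectral classifier.

    Parameters
    ----------
    kernel_size, sigma : Gaussian filter window (odd taps) and width in
        channels; the conventional 5 / 1.5 defaults.
    smooth : toggle the filtering stage.
    select : toggle channel selection ("raw-input fusion" baseline when off).
    top_k : relevance cutoff; None triggers a validation grid search.
    spearman_threshold : redundancy threshold tau; None triggers a grid
        search (``tau_grid``); set ``prune=False`` to skip pruning entirely.
    prune : toggle the redundancy stage.
    bins : MIC discretization bins (None: min(16, ceil(sqrt(n)))).
    k_grid, tau_grid : (min, max, step) grids used when top_k /
        spearman_threshold is None; searches score a scaled RBF-SVM on the
        validation split.
    tune : when True, sub-model hyperparameters are grid-searched on the
        validation split; otherwise fixed documented defaults are used.
    weight_mode : "validation" (canonical) or "train" — where fusion weights
        P_i * R_i are measured.
    random_state : seeds stochastic sub-models.

    Attributes
    ----------
    smoother_, selector_, fusion_ : the fitted stage estimators
    selection_ : :class:`SelectionResult` (None when ``select=False``)
    top_k_, spearman_threshold_ : the values actually used
    classes_ : class labels
    """

    def __init__(
        self,
        kernel_size: int = 5,
        sigma: float = 1.5,
        smooth: bool = True,
        select: bool = True,
        top_k: int | None = 300,
        spearman_threshold: float | None = 0.9,
        prune: bool = True,
        bins: int | None = None,
        k_grid: tuple = (50, 1000, 50),
        tau_grid: tuple = (0.80, 0.99, 0.01),
        tune: bool = True,
        weight_mode: str = "validation",
        random_state: int | None = 0,
    ):
        self.kernel_size = kernel_size
        self.sigma = sigma
        self.smooth = smooth
        self.select = select
        self.top_k = top_k
        self.spearman_threshold = spearman_threshold
        self.prune = prune
        self.bins = bins
        self.k_grid = k_grid
        self.tau_grid = tau_grid
        self.tune = tune
        self.weight_mode = weight_mode
        self.random_state = random_state

    def fit(self, dataset: SpectralDataset):
        """Fit all stages from a dataset carrying train/validation tags."""
        dataset.require_min_classes(2)
        if dataset.split is None:
            raise ValueError("dataset must carry split tags; call split_dataset")
        if self.weight_mode not in ("validation", "train"):
            raise ValueError("weight_mode must be 'validation' or 'train'")
        work = dataset
        if self.smooth:
            self.smoother_ = GaussianSmoother(self.kernel_size, self.sigma)
            self.smoother_.fit(work.intensities)
            work = work.with_intensities(self.smoother_.transform(work.intensities))
        else:
            self.smoother_ = None

        train = work.split_part("train")
        val = work.split_part("validation")

        if self.select:
            top_k = self.top_k
            if top_k is None:
                top_k = grid_search_k(
                    work, "svm", *self.k_grid, bins=self.bins,
                    random_state=self.random_state,
                ).best
            tau = self.spearman_threshold
            if self.prune and tau is None:
                tau = grid_search_threshold(
                    work, "svm", top_k, *self.tau_grid, bins=self.bins,
                    random_state=self.random_state,
                ).best
            self.selector_ = StackedFeatureSelector(
                top_k=top_k,
                spearman_threshold=tau if self.prune else None,
                bins=self.bins,
            ).fit(train.intensities, train.labels)
            self.selection_ = self.selector_.result_
            self.top_k_, self.spearman_threshold_ = top_k, tau if self.prune else None
            X_tr = self.selector_.transform(train.intensities)
            X_val = self.selector_.transform(val.intensities)
        else:
            self.selector_ = None
            self.selection_ = None
            self.top_k_ = self.spearman_threshold_ = None
            X_tr, X_val = train.intensities, val.intensities

        submodels = (
            tune_submodels(
                X_tr, train.labels, X_val, val.labels, random_state=self.random_state
            )
            if self.tune
            else None
        )
        self.fusion_ = FusionClassifier(
            submodels=submodels, random_state=self.random_state
        )
        if self.weight_mode == "train":
            self.fusion_.set_params(weight_mode="train")
            self.fusion_.fit(X_tr, train.labels)
        else:
            self.fusion_.fit(X_tr, train.labels, X_val, val.labels)
        self.classes_ = self.fusion_.classes_
        self.n_features_in_ = dataset.n_channels
        return self

    def _prepare(self, intensities: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(intensities, dtype=float))
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} channels, got {X.shape[1]}"
            )
        if self.smoother_ is not None:
            X = self.smoother_.transform(X)
        if self.selector_ is not None:
            X = self.selector_.transform(X)
        return X

    def predict(self, intensities):
        check_is_fitted(self)
        return self.fusion_.predict(self._prepare(intensities))

    def decision_scores(self, intensities):
        check_is_fitted(self)
        return self.fusion_.decision_scores(self._prepare(intensities))

    def score_split(self, dataset: SpectralDataset, tag: str = "test") -> float:
        part = dataset.split_part(tag)
        return float(np.mean(self.predict(part.intensities) == part.labels))


def fit_pipeline(dataset: SpectralDataset, **params) -> tuple[SpectralPipeline, SelectionResult | None]:
    """Functional wrapper: fit a :class:`SpectralPipeline` and return it with
    its selection result."""
    pipe = SpectralPipeline(**params).fit(dataset)
    return pipe, pipe.selection_
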