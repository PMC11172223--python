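"""Discrete Gaussian filtering of spectra.

High-frequency noise in broadband emission spectra is suppressed by a
weighted moving average whose weights follow the Gaussian density
``G(x) = exp(-x^2 / 2 sigma^2)`` evaluated at integer channel offsets ``x``
from the window center and renormalized to sum to one (the continuous
``1/sqrt(2 pi sigma^2)`` prefactor cancels under renormalization). Default
window: 5 taps with sigma = 1.5 channels.

Boundaries use reflect padding, which keeps a constant spectrum exactly
fixed and avoids edge darkening from a truncated kernel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import convolve1d
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .dataset import SpectralDataset


@dataclass(frozen=True)
class GaussianKernel:
    """Normalized discrete Gaussian smoothing weights.

    ``size`` is the odd tap count; ``sigma`` the standard deviation in
    channel units. Weights are symmetric, positive, sum to one, and peak at
    the center tap.
    """

    size: int
    sigma: float
    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        assert w.shape == (self.size,)
        assert abs(w.sum() - 1.0) < 1e-12


def build_kernel(size: int = 5, sigma: float = 1.5) -> GaussianKernel:
    """Build the discrete kernel; size must be odd and >= 1, sigma > 0."""
    if size < 1 or size % 2 == 0:
        raise ValueError(f"kernel size must be a positive odd integer, got {size}")
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    x = np.arange(size, dtype=float) - (size - 1) / 2
    w = np.exp(-(x**2) / (2.0 * sigma**2))
    return GaussianKernel(size=size, sigma=float(sigma), weights=w / w.sum())


class GaussianSmoother(TransformerMixin, BaseEstimator):
    """Per-spectrum Gaussian filter as a scikit-learn transformer.

    Parameters
    ----------
    size : odd int, default 5
        Window width in channels.
    sigma : float, default 1.5
        Kernel standard deviation in channels.

    Each row of X is convolved independently along the wavelength axis with
    reflect-padded boundaries; every output value is a convex combination of
    input values inside its window.
    """

    def __init__(self, size: int = 5, sigma: float = 1.5):
        self.size = size
        self.sigma = sigma

    def fit(self, X, y=None):
        X = check_array(X)
        self.kernel_ = build_kernel(self.size, self.sigma)
        if self.kernel_.size > X.shape[1]:
            raise ValueError(
                f"kernel of {self.kernel_.size} taps is wider than the "
                f"{X.shape[1]}-channel axis"
            )
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self)
        X = check_array(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("channel count changed between fit and transform")
        # ndimage "reflect" = symmetric padding (a b c | c b a)
        return convolve1d(X, self.kernel_.weights, axis=1, mode="reflect")


def smooth(dataset: SpectralDataset, kernel: GaussianKernel | None = None) -> SpectralDataset:
    """Smooth every spectrum of a dataset; wavelengths/labels/split unchanged."""
    if kernel is None:
        kernel = build_kernel()
    smoother = GaussianSmoother(size=kernel.size, sigma=kernel.sigma)
    return dataset.with_intensities(
        smoother.fit(dataset.intensities).transform(dataset.intensities)
    )
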