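"""Spectral dataset container and CSV round-trip.

A :class:`SpectralDataset` is the in-memory unit every stage operates on: a
shared, strictly increasing wavelength axis (nm), one intensity row per
spectrum, a class label per spectrum, and an optional train/validation/test
split tag.

On disk a dataset is a plain UTF-8 CSV: a ``label`` column, an optional
``split`` column, and one column per channel whose header is the wavelength in
nm written as a decimal string.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

SPLIT_TAGS = ("train", "validation", "test")


class FormatError(ValueError):
    """Raised when an on-disk dataset violates the CSV contract."""


@dataclass
class SpectralDataset:
    """Matrix of spectra sharing one wavelength axis.

    Parameters
    ----------
    wavelengths : (n_channels,) array, strictly increasing, in nm.
    intensities : (n_spectra, n_channels) array of finite intensities
        (arbitrary units).
    labels : (n_spectra,) array of class identifiers.
    split : optional (n_spectra,) array of tags in
        ``{"train", "validation", "test"}``.
    """

    wavelengths: np.ndarray
    intensities: np.ndarray
    labels: np.ndarray
    split: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.intensities = np.atleast_2d(np.asarray(self.intensities, dtype=float))
        self.labels = np.asarray(self.labels)
        if self.wavelengths.ndim != 1:
            raise ValueError("wavelengths must be one-dimensional")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")
        if self.intensities.shape[1] != self.wavelengths.size:
            raise ValueError(
                f"intensities have {self.intensities.shape[1]} channels but the "
                f"wavelength axis has {self.wavelengths.size}"
            )
        if self.labels.shape != (self.intensities.shape[0],):
            raise ValueError("one label is required per spectrum")
        if self.split is not None:
            self.split = np.asarray(self.split, dtype=object)
            if self.split.shape != self.labels.shape:
                raise ValueError("one split tag is required per spectrum")
            bad = set(self.split) - set(SPLIT_TAGS)
            if bad:
                raise ValueError(f"unknown split tags: {sorted(bad)}")

    @property
    def n_spectra(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_channels(self) -> int:
        return self.intensities.shape[1]

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.labels)

    def subset(self, mask: np.ndarray) -> "SpectralDataset":
        """Row subset (boolean mask or index array); wavelength axis shared."""
        mask = np.asarray(mask)
        return SpectralDataset(
            wavelengths=self.wavelengths,
            intensities=self.intensities[mask],
            labels=self.labels[mask],
            split=None if self.split is None else self.split[mask],
        )

    def split_part(self, tag: str) -> "SpectralDataset":
        """Rows carrying one split tag."""
        if self.split is None:
            raise ValueError("dataset carries no split tags; call split_dataset first")
        if tag not in SPLIT_TAGS:
            raise ValueError(f"unknown split tag {tag!r}")
        return self.subset(self.split == tag)

    def with_intensities(self, intensities: np.ndarray) -> "SpectralDataset":
        """Same axis/labels/split with replaced intensity matrix."""
        return replace(self, intensities=np.asarray(intensities, dtype=float))

    def require_min_classes(self, k: int = 2) -> None:
        if self.classes.size < k:
            raise ValueError(
                f"operation requires at least {k} classes; dataset has "
                f"{self.classes.size}"
            )


def write_dataset(dataset: SpectralDataset, path: str | Path) -> None:
    """Write a dataset as a label/split/wavelength-column CSV."""
    cols: dict[str, np.ndarray] = {"label": dataset.labels}
    if dataset.split is not None:
        cols["split"] = dataset.split
    frame = pd.DataFrame(cols)
    spectra = pd.DataFrame(
        dataset.intensities,
        columns=[repr(float(w)) for w in dataset.wavelengths],
    )
    pd.concat([frame, spectra], axis=1).to_csv(path, index=False)


def read_dataset(path: str | Path, label_column: str = "label") -> SpectralDataset:
    """Read a dataset CSV; see module docstring for the layout.

    Raises :class:`FormatError` with row/column context for a missing label
    column, non-numeric wavelength headers or cells, and a non-increasing
    wavelength axis.
    """
    frame = pd.read_csv(path, dtype={label_column: object})
    if label_column not in frame.columns:
        raise FormatError(
            f"{path}: label column {label_column!r} not found "
            f"(columns start with {list(frame.columns[:3])})"
        )
    labels = frame.pop(label_column).to_numpy(dtype=object)
    split = None
    if "split" in frame.columns:
        split = frame.pop("split").to_numpy(dtype=object)

    try:
        wavelengths = np.array([float(c) for c in frame.columns])
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric wavelength header: {exc}") from exc
    if wavelengths.size and np.any(np.diff(wavelengths) <= 0):
        j = int(np.flatnonzero(np.diff(wavelengths) <= 0)[0])
        raise FormatError(
            f"{path}: wavelength header not strictly increasing at column "
            f"{j + 1} ({frame.columns[j]} -> {frame.columns[j + 1]})"
        )
    try:
        intensities = frame.to_numpy(dtype=float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric intensity cell: {exc}") from exc
    if not np.all(np.isfinite(intensities)):
        r, c = np.argwhere(~np.isfinite(intensities))[0]
        raise FormatError(
            f"{path}: non-finite intensity at row {int(r) + 2}, "
            f"column {frame.columns[int(c)]}"
        )
    return SpectralDataset(
        wavelengths=wavelengths,
        intensities=intensities,
        labels=labels,
        split=split,
    )
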