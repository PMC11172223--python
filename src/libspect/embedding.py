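"""t-SNE diagnostics with per-class marginal normal curves.

Each pipeline stage's data matrix is reduced to two dimensions with t-SNE
(PCA initialization, fixed seed) and drawn as a scatter plot; for every
class, axis-wise normal curves (sample mean and sd of that class's embedded
coordinates) are drawn in the top and right margins on a shared density
scale. Tightly clustered classes show tall narrow curves; well-separated
classes show little curve overlap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset import SpectralDataset


@dataclass
class EmbeddingView:
    """2-D embedding plus per-class axis-wise normal fits."""

    coordinates: np.ndarray  # (n_samples, 2)
    labels: np.ndarray
    class_stats: dict  # class -> {"mean": (2,), "sd": (2,)}

    def __post_init__(self) -> None:
        assert self.coordinates.shape == (len(self.labels), 2)


def embed(
    data: SpectralDataset | np.ndarray,
    perplexity: float = 30.0,
    seed: int = 0,
    labels=None,
) -> EmbeddingView:
    """Seeded 2-D t-SNE embedding of spectra or a selected-feature matrix.

    ``perplexity`` must be below the sample count. Classes with >= 2 points
    get positive per-axis sds (degenerate single-point classes get sd 0).
    """
    from sklearn.manifold import TSNE

    if isinstance(data, SpectralDataset):
        X, labels = data.intensities, data.labels
    else:
        X = np.asarray(data, dtype=float)
        if labels is None:
            raise ValueError("labels are required with a bare feature matrix")
        labels = np.asarray(labels)
    n = X.shape[0]
    if n < 2:
        raise ValueError("embedding requires at least two samples")
    if perplexity >= n:
        raise ValueError(f"perplexity ({perplexity}) must be below n_samples ({n})")
    coords = TSNE(
        n_components=2,
        perplexity=perplexity,
        init="pca",
        random_state=seed,
    ).fit_transform(X)
    stats = {}
    for cls in np.unique(labels):
        pts = coords[labels == cls]
        stats[cls] = {
            "mean": pts.mean(axis=0),
            "sd": pts.std(axis=0, ddof=1) if len(pts) > 1 else np.zeros(2),
        }
    return EmbeddingView(coordinates=coords, labels=labels, class_stats=stats)


def plot_embedding(view: EmbeddingView, ax, title: str = "") -> None:
    """Scatter plot with marginal per-class normal curves above and to the
    right, on one shared density scale per axis."""
    import matplotlib.pyplot as plt  # noqa: F401  (backend already selected)
    from mpl_toolkits.axes_grid1 import make_axes_locatable

    classes = np.unique(view.labels)
    cmap = plt.get_cmap("tab10" if len(classes) <= 10 else "tab20")
    divider = make_axes_locatable(ax)
    ax_top = divider.append_axes("top", size="22%", pad=0.05, sharex=ax)
    ax_right = divider.append_axes("right", size="22%", pad=0.05, sharey=ax)
    for extra in (ax_top, ax_right):
        extra.tick_params(labelbottom=False, labelleft=False)

    for i, cls in enumerate(classes):
        color = cmap(i % cmap.N)
        pts = view.coordinates[view.labels == cls]
        ax.scatter(pts[:, 0], pts[:, 1], s=8, color=color, label=str(cls))
        mean, sd = view.class_stats[cls]["mean"], view.class_stats[cls]["sd"]
        for axis, target in ((0, ax_top), (1, ax_right)):
            if sd[axis] <= 0:
                continue
            grid = np.linspace(
                mean[axis] - 4 * sd[axis], mean[axis] + 4 * sd[axis], 200
            )
            density = np.exp(-0.5 * ((grid - mean[axis]) / sd[axis]) ** 2) / (
                sd[axis] * np.sqrt(2 * np.pi)
            )
            if axis == 0:
                target.plot(grid, density, color=color, lw=1)
            else:
                target.plot(density, grid, color=color, lw=1)
    ax_top.set_title(title)


def stage_panel_figure(views: dict[str, EmbeddingView], path=None):
    """Four-panel diagnostic figure in the fixed order raw / smoothed /
    single-selection / stacked-selection (panels with other names follow in
    insertion order)."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    preferred = ["raw", "smoothed", "single_selection", "stacked_selection"]
    names = [n for n in preferred if n in views]
    names += [n for n in views if n not in names]
    fig, axes = plt.subplots(2, 2, figsize=(11, 10))
    for ax, name in zip(axes.ravel(), names):
        plot_embedding(views[name], ax, title=name.replace("_", " "))
    for ax in axes.ravel()[len(names):]:
        ax.axis("off")
    handles, labels_ = axes.ravel()[0].get_legend_handles_labels()
    fig.legend(handles, labels_, loc="lower center", ncol=min(10, len(labels_)))
    fig.tight_layout(rect=(0, 0.05, 1, 1))
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
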