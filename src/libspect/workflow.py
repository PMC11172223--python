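"""End-to-end orchestration: configuration, artifacts, logging, diagnostics.

``run_all`` executes simulate/read -> split -> smooth -> select -> fuse ->
evaluate -> visualize and writes five artifacts: the smoothed spectra CSV,
the selection JSON, the model JSON (with a joblib sidecar holding fitted
sub-model state), the evaluation report JSON, and a four-panel t-SNE figure
(raw / smoothed / single-selection / stacked-selection). Given the same
configuration and seed, the JSON artifacts are byte-identical across runs.

Configuration lives in a plain ``key = value`` text file mirroring
:class:`PipelineConfig` field names; logging goes to standard error and
never influences artifact content.
"""

from __future__ import annotations

import ast
import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np

from . import simulate
from .dataset import SpectralDataset, read_dataset, write_dataset
from .embedding import embed, stage_panel_figure
from .evaluation import compute_report, split_dataset
from .pipeline import SpectralPipeline

log = logging.getLogger("libspect")


@dataclass
class PipelineConfig:
    """Everything one ``run_all`` invocation needs.

    ``input_csv=None`` simulates a dataset from the ``sim_*`` fields instead
    of reading one. All stage parameters are validated against their stage's
    preconditions before any stage runs.
    """

    # input
    input_csv: str | None = None
    label_column: str = "label"
    sim_n_classes: int = 10
    sim_spectra_per_class: int = 90
    sim_n_channels: int = 4000
    sim_noise_sd: float = 60.0
    sim_shot_noise_scale: float = 0.2
    # stage toggles
    smooth: bool = True
    select: bool = True
    fuse: bool = True
    # stage parameters
    kernel_size: int = 5
    sigma: float = 1.5
    bins: int | None = None
    top_k: int | None = 300
    spearman_threshold: float | None = 0.9
    prune: bool = True
    k_grid: tuple = (50, 1000, 50)
    tau_grid: tuple = (0.80, 0.99, 0.01)
    tune: bool = True
    weight_mode: str = "validation"
    split_proportions: tuple = (0.6, 0.2, 0.2)
    perplexity: float = 30.0
    embed_max_samples: int = 1000
    seed: int = 0
    # outputs
    out_dir: str = "libspect_out"
    smoothed_csv: str = "smoothed.csv"
    selection_json: str = "selection.json"
    model_json: str = "model.json"
    report_json: str = "report.json"
    figure_png: str = "embedding.png"

    def validate(self) -> None:
        from .smoothing import build_kernel

        build_kernel(self.kernel_size, self.sigma)
        tau = self.spearman_threshold
        if tau is not None and not 0.0 < tau <= 1.0:
            raise ValueError(f"spearman_threshold must be in (0, 1], got {tau}")
        if self.top_k is not None and self.top_k < 1:
            raise ValueError("top_k must be positive")
        props = np.asarray(self.split_proportions, dtype=float)
        if props.shape != (3,) or abs(props.sum() - 1.0) > 1e-9 or np.any(props < 0):
            raise ValueError("split_proportions must be 3 non-negative values summing to 1")
        if self.perplexity <= 0:
            raise ValueError("perplexity must be positive")
        if self.weight_mode not in ("validation", "train"):
            raise ValueError("weight_mode must be 'validation' or 'train'")
        if self.input_csv is None:
            simulate.default_config(
                n_classes=self.sim_n_classes,
                spectra_per_class=self.sim_spectra_per_class,
                n_channels=self.sim_n_channels,
                noise_sd=self.sim_noise_sd,
                shot_noise_scale=self.sim_shot_noise_scale,
                seed=self.seed,
            )

    # -------------------------------------------------- plain-text key=value

    def to_file(self, path: str | Path) -> None:
        lines = [
            f"{f.name} = {getattr(self, f.name)!r}"
            for f in dataclasses.fields(self)
        ]
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        known = {f.name: f for f in dataclasses.fields(cls)}
        values: dict = {}
        for lineno, raw in enumerate(
            Path(path).read_text(encoding="utf-8").splitlines(), start=1
        ):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, _, value = (s.strip() for s in line.partition("="))
            if key not in known:
                raise ValueError(f"{path}:{lineno}: unknown parameter {key!r}")
            try:
                values[key] = ast.literal_eval(value)
            except (ValueError, SyntaxError):
                values[key] = value  # bare string
        return cls(**values)


def _json_dump(obj, path: Path) -> None:
    path.write_text(
        json.dumps(obj, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _load_or_simulate(config: PipelineConfig) -> SpectralDataset:
    if config.input_csv is not None:
        return read_dataset(config.input_csv, config.label_column)
    sim = simulate.default_config(
        n_classes=config.sim_n_classes,
        spectra_per_class=config.sim_spectra_per_class,
        n_channels=config.sim_n_channels,
        noise_sd=config.sim_noise_sd,
        shot_noise_scale=config.sim_shot_noise_scale,
        seed=config.seed,
    )
    return simulate.simulate_dataset(sim)


def run_all(config: PipelineConfig) -> dict[str, Path]:
    """Execute the full workflow; returns the artifact paths.

    Any stage failure raises :class:`StageError` naming the stage; artifacts
    written before the failure remain on disk (partial state).
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    timer = time.perf_counter

    def stage(name):
        def deco(fn):
            t0 = timer()
            try:
                result = fn()
            except StageError:
                raise
            except Exception as exc:  # noqa: BLE001 — reported with stage name
                if artifacts:
                    log.error(
                        "partial artifacts on disk: %s",
                        {k: str(v) for k, v in artifacts.items()},
                    )
                raise StageError(name, exc) from exc
            log.info("stage %-10s done in %.2fs", name, timer() - t0)
            return result

        return deco

    dataset = stage("input")(lambda: _load_or_simulate(config))
    if dataset.split is None:
        dataset = stage("split")(
            lambda: split_dataset(dataset, config.split_proportions, config.seed)
        )

    def _fit():
        pipe = SpectralPipeline(
            kernel_size=config.kernel_size,
            sigma=config.sigma,
            smooth=config.smooth,
            select=config.select,
            top_k=config.top_k,
            spearman_threshold=config.spearman_threshold,
            prune=config.prune,
            bins=config.bins,
            k_grid=tuple(config.k_grid),
            tau_grid=tuple(config.tau_grid),
            tune=config.tune,
            weight_mode=config.weight_mode,
            random_state=config.seed,
        )
        return pipe.fit(dataset)

    pipe = stage("fit")(_fit)
    if config.select:
        log.info(
            "selection: k=%s tau=%s -> %d channels",
            pipe.top_k_, pipe.spearman_threshold_, pipe.selection_.selected.size,
        )
    log.info("fusion weights:\n%s", np.array_str(pipe.fusion_.weights_.matrix, precision=3))

    def _write_smoothed():
        smoothed = (
            dataset.with_intensities(pipe.smoother_.transform(dataset.intensities))
            if config.smooth
            else dataset
        )
        path = out_dir / config.smoothed_csv
        write_dataset(smoothed, path)
        artifacts["smoothed_csv"] = path
        return smoothed

    smoothed = stage("smooth")(_write_smoothed)

    def _write_selection():
        path = out_dir / config.selection_json
        payload = (
            {
                **pipe.selection_.to_dict(),
                "chosen_k": pipe.top_k_,
                "chosen_tau": pipe.spearman_threshold_,
            }
            if config.select
            else {"selected": list(range(dataset.n_channels)), "chosen_k": None,
                  "chosen_tau": None}
        )
        _json_dump(payload, path)
        artifacts["selection_json"] = path

    stage("select")(_write_selection)

    def _write_model():
        sidecar = out_dir / (Path(config.model_json).stem + ".joblib")
        joblib.dump(pipe, sidecar)
        payload = {
            "submodels": [
                {"name": name, "spec": repr(est)}
                for name, est in pipe.fusion_.submodels_
            ],
            "classes": [str(c) for c in pipe.classes_],
            "weight_matrix": pipe.fusion_.weights_.matrix.tolist(),
            "tie_breaker": pipe.fusion_.submodels_[pipe.fusion_.tie_breaker_][0],
            "fitted_parameters": sidecar.name,
        }
        path = out_dir / config.model_json
        _json_dump(payload, path)
        artifacts["model_json"] = path
        artifacts["model_joblib"] = sidecar

    stage("train")(_write_model)

    def _write_report():
        test = dataset.split_part("test")
        report = compute_report(
            test.labels, pipe.predict(test.intensities), class_order=dataset.classes
        )
        path = out_dir / config.report_json
        _json_dump(report.to_dict(), path)
        artifacts["report_json"] = path
        log.info("test accuracy %.4f  macro F1 %.4f", report.accuracy, report.macro_f1)

    stage("evaluate")(_write_report)

    def _figure():
        n = dataset.n_spectra
        rng = np.random.default_rng(config.seed)
        idx = (
            np.sort(rng.choice(n, config.embed_max_samples, replace=False))
            if n > config.embed_max_samples
            else np.arange(n)
        )
        raw, smo = dataset.subset(idx), smoothed.subset(idx)
        perplexity = min(config.perplexity, (idx.size - 1) / 3)
        views = {
            "raw": embed(raw, perplexity, config.seed),
            "smoothed": embed(smo, perplexity, config.seed),
        }
        if config.select:
            top = pipe.selection_.rank_order[: pipe.selection_.top_k]
            views["single_selection"] = embed(
                smo.intensities[:, top], perplexity, config.seed, labels=smo.labels
            )
            views["stacked_selection"] = embed(
                smo.intensities[:, pipe.selection_.selected],
                perplexity,
                config.seed,
                labels=smo.labels,
            )
        path = out_dir / config.figure_png
        stage_panel_figure(views, path)
        artifacts["figure_png"] = path

    stage("visualize")(_figure)
    return artifacts
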