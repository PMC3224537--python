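"""Run configuration and the end-to-end experiment driver.

A RunConfig fully determines one evaluation: input source (synthetic
spec or image directory + manifest), extractor, component count, CV
settings and seeds.  ``run_experiment`` executes
load/simulate -> preprocess -> fit/select/classify -> evaluate and
writes the report, a metrics CSV, a basis montage and the resolved
config next to each other, so every output is reproducible from the
persisted file alone.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .datatypes import ROIDataset
from .evaluation import EvalReport, MethodConfig, crossvalidate
from .gabor import GaborParams, gabor_bank
from .ica import fit_efficient_coding
from .pca import pca_fit
from .preprocess import load_dataset
from .synthetic import SynthParams, generate_dataset

__all__ = ["RunConfig", "load_config", "save_config", "run_experiment"]


@dataclass
class RunConfig:
    """Serializable description of one experiment."""

    method: str = "pca"
    n_components: int = 10
    folds: int = 10
    seed: int = 0
    image_size: int = 32
    # input: either a synthetic per-class count spec ...
    synthetic: dict[str, int] | None = None
    blob_contrast: float = 0.8
    # ... or a manifest of images on disk
    manifest: str | None = None
    # extractor details
    ica_candidates: int | None = None
    ica_max_iter: int = 200
    ica_tol: float = 1e-4
    ica_contrast: str = "logcosh"
    gabor_scales: int = 10
    gabor_orientations: int = 10
    criterion: str = "accuracy"
    output_dir: str = "runs/latest"

    def __post_init__(self) -> None:
        if self.method not in ("pca", "ica", "gabor"):
            raise ValueError(
                f"invalid field 'method': {self.method!r} "
                "(expected pca, ica or gabor)"
            )
        if self.synthetic is None and self.manifest is None:
            raise ValueError(
                "invalid input source: set either 'synthetic' or 'manifest'"
            )
        if self.n_components < 1:
            raise ValueError("invalid field 'n_components': must be >= 1")
        if self.folds < 2:
            raise ValueError("invalid field 'folds': must be >= 2")

    def method_config(self) -> MethodConfig:
        return MethodConfig(
            method=self.method,
            ica_candidates=self.ica_candidates,
            ica_contrast=self.ica_contrast,
            ica_max_iter=self.ica_max_iter,
            ica_tol=self.ica_tol,
            gabor=GaborParams(n_scales=self.gabor_scales,
                              n_orientations=self.gabor_orientations,
                              grid_side=self.image_size),
            criterion=self.criterion,
        )

    def load_data(self) -> ROIDataset:
        if self.synthetic is not None:
            params = SynthParams(image_size=self.image_size,
                                 blob_contrast=self.blob_contrast,
                                 seed=self.seed)
            return generate_dataset(self.synthetic, params)
        return load_dataset(self.manifest, side=self.image_size)


def save_config(config: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=True)


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config fields: {sorted(unknown)}")
    return RunConfig(**raw)


def _save_montage(config: RunConfig, dataset: ROIDataset, out: Path) -> None:
    """Figure-style montage of the first 25 basis images of the chosen
    extractor, fitted once on the full dataset."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    side = config.image_size
    if config.method == "pca":
        vectors = pca_fit(dataset).components
    elif config.method == "ica":
        pool = config.ica_candidates or max(config.n_components, 25)
        model = fit_efficient_coding(
            dataset, n_components=min(pool, 25),
            max_iter=config.ica_max_iter, tol=config.ica_tol,
            seed=config.seed)
        vectors = model.basis
    else:
        vectors = gabor_bank(config.method_config().gabor).vectors
    n = min(25, vectors.shape[1])
    fig, axes = plt.subplots(5, 5, figsize=(6, 6))
    for i, ax in enumerate(axes.ravel()):
        ax.axis("off")
        if i < n:
            ax.imshow(vectors[:, i].reshape(side, side), cmap="gray")
    fig.suptitle(f"{config.method} basis images")
    fig.savefig(out, dpi=100)
    plt.close(fig)


def run_experiment(config: RunConfig, montage: bool = True) -> EvalReport:
    """Execute one configured evaluation and persist its artifacts.

    Writes config.yaml, report.json, metrics.csv and (optionally)
    basis.png into config.output_dir; returns the EvalReport.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_config(config, out / "config.yaml")

    dataset = config.load_data()
    report = crossvalidate(dataset, config.method_config(),
                           config.n_components, k=config.folds,
                           seed=config.seed)
    with open(out / "report.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=2)

    rows = ["fold,accuracy,sensitivity,specificity"]
    for entry in report.per_fold:
        m = entry["metrics"]
        rows.append(",".join(
            [str(entry["fold"])]
            + [("" if m[k] is None else f"{m[k]:.6f}")
               for k in ("accuracy", "sensitivity", "specificity")]
        ))
    rows.append(",".join([
        "mean",
        f"{report.mean_accuracy:.6f}",
        f"{report.mean_sensitivity:.6f}",
        f"{report.mean_specificity:.6f}",
    ]))
    (out / "metrics.csv").write_text("\n".join(rows) + "\n")

    if montage:
        _save_montage(config, dataset, out / "basis.png")
    return report
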