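"""Stratified k-fold evaluation of (extractor, selection, LDA) pipelines.

Every fold fits the extractor (PCA basis / FastICA model / Gabor
selection) and the discriminant on the training portion only, then
scores the held-out fold; accuracy, sensitivity and specificity are
averaged over folds with equal weight (stratification keeps fold sizes
within one sample of each other per class).

The component sweep reuses the per-fold fit: greedy selection orders
the candidates once up to the largest requested count, and each smaller
count reads a prefix of that order; PCA prefixes are the variance
order.  This makes the sweep a single extractor fit per fold instead of
one per (fold, count) pair, and is exact because greedy forward
selection is prefix-consistent by construction.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from .datatypes import FeatureMatrix, ROIDataset
from .gabor import GaborParams, gabor_bank, gabor_project
from .ica import fastica_fit, whiten
from .lda import lda_fit, lda_predict
from .pca import pca_fit, pca_project
from .selection import greedy_select

__all__ = [
    "ConfusionCounts",
    "EvalReport",
    "MethodConfig",
    "compute_metrics",
    "stratified_kfold",
    "crossvalidate",
    "component_sweep",
]

METHODS = ("pca", "ica", "gabor")


@dataclass
class ConfusionCounts:
    """TP = disease-class samples correctly flagged; the rest analogous."""

    TP: int = 0
    TN: int = 0
    FP: int = 0
    FN: int = 0

    def __post_init__(self) -> None:
        for name in ("TP", "TN", "FP", "FN"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.TP + other.TP, self.TN + other.TN,
                               self.FP + other.FP, self.FN + other.FN)


def compute_metrics(c: ConfusionCounts) -> dict[str, float | None]:
    """accuracy, sensitivity = TP/(TP+FN), specificity = TN/(TN+FP).

    A ratio with an empty denominator is reported as None (absent),
    never coerced to zero.
    """
    out: dict[str, float | None] = {}
    out["accuracy"] = ((c.TP + c.TN) / c.total) if c.total else None
    out["sensitivity"] = (c.TP / (c.TP + c.FN)) if (c.TP + c.FN) else None
    out["specificity"] = (c.TN / (c.TN + c.FP)) if (c.TN + c.FP) else None
    return out


def stratified_kfold(labels, k: int, seed: int = 0) -> np.ndarray:
    """Deterministic stratified fold assignment.

    Returns an integer array fold[i] in [0, k); folds are disjoint,
    cover every sample, and per-class counts differ by at most one
    across folds.  Each class is permuted by the seeded RNG and split
    into k nearly-equal runs.
    """
    y = np.asarray(labels)
    if k < 2:
        raise ValueError("need at least 2 folds")
    rng = np.random.default_rng(seed)
    folds = np.empty(y.shape[0], dtype=int)
    for cls in sorted(np.unique(y).tolist()):
        idx = np.flatnonzero(y == cls)
        if idx.size < k:
            raise ValueError(
                f"class {cls!r} has {idx.size} samples, fewer than k={k}"
            )
        perm = rng.permutation(idx)
        for f, part in enumerate(np.array_split(perm, k)):
            folds[part] = f
    return folds


@dataclass
class MethodConfig:
    """Extractor + selection configuration for one CV run.

    For ICA, ``ica_candidates`` caps the whitened dimension the
    FastICA fit works in — the candidate pool the greedy wrapper
    chooses from.  None (the default) matches the pool to the requested
    component count: with a training-accuracy wrapper, a pool of
    amplified unit-variance directions much larger than the sample
    support invites overfitted picks, so by default FastICA itself does
    the compression and the wrapper orders its output.  Gabor
    candidates are always the full bank.  PCA uses variance ordering
    and ignores the selection settings.
    """

    method: str = "pca"
    ica_candidates: int | None = None
    ica_contrast: str = "logcosh"
    ica_max_iter: int = 200
    ica_tol: float = 1e-4
    gabor: GaborParams = field(default_factory=GaborParams)
    criterion: str = "accuracy"

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(
                f"unknown method {self.method!r}; expected one of {METHODS}"
            )


@dataclass
class EvalReport:
    """Per-fold confusion counts and metrics plus their fold averages."""

    per_fold: list[dict]
    mean_accuracy: float
    mean_sensitivity: float
    mean_specificity: float
    config: dict

    def to_dict(self) -> dict:
        return asdict(self)


def _positive_class(labels: np.ndarray) -> Any:
    classes = sorted(np.unique(labels).tolist())
    for preferred in ("mass", "malignant"):
        if preferred in classes:
            return preferred
    return classes[-1]


def _confusion(y_true, y_pred, positive) -> ConfusionCounts:
    pos = y_true == positive
    hit = y_pred == positive
    return ConfusionCounts(
        TP=int(np.count_nonzero(pos & hit)),
        TN=int(np.count_nonzero(~pos & ~hit)),
        FP=int(np.count_nonzero(~pos & hit)),
        FN=int(np.count_nonzero(pos & ~hit)),
    )


def _fold_features(
    train: ROIDataset,
    test: ROIDataset,
    cfg: MethodConfig,
    c_max: int,
    seed: int,
    positive,
) -> tuple[np.ndarray, np.ndarray, list[int]]:
    """Fit extractor (+ greedy selection) on the training fold only.

    Returns training and test coefficient matrices whose rows are
    already in selection (or variance) order, truncated at c_max, plus
    the candidate order used.
    """
    if cfg.method == "pca":
        basis = pca_fit(train)
        if c_max > basis.n_components:
            raise ValueError(
                f"requested {c_max} components but PCA basis has only "
                f"{basis.n_components}"
            )
        Ftr = pca_project(train, basis, c_max).coeffs
        Fte = pca_project(test, basis, c_max).coeffs
        return Ftr, Fte, list(range(c_max))

    if cfg.method == "ica":
        pool = cfg.ica_candidates if cfg.ica_candidates is not None else c_max
        z, wm = whiten(train, n_components=pool)
        model = fastica_fit(z, wm, contrast=cfg.ica_contrast,
                            max_iter=cfg.ica_max_iter, tol=cfg.ica_tol,
                            seed=seed)
        Xtr = train.data - wm.mean[:, None]
        Xte = test.data - wm.mean[:, None]
        all_tr = model.filters @ Xtr
        all_te = model.filters @ Xte
    else:  # gabor: fixed data-independent bank, greedy over its filters
        bank = gabor_bank(cfg.gabor)
        mean = train.data.mean(axis=1)
        all_tr = bank.vectors.T @ (train.data - mean[:, None])
        all_te = bank.vectors.T @ (test.data - mean[:, None])

    if c_max > all_tr.shape[0]:
        raise ValueError(
            f"requested {c_max} components but only {all_tr.shape[0]} "
            f"candidates are available"
        )
    sel = greedy_select(FeatureMatrix(coeffs=all_tr, labels=train.labels),
                        c_max, criterion=cfg.criterion,
                        positive_class=positive)
    order = sel.selected_indices
    return all_tr[order], all_te[order], order


def _run_folds(
    dataset: ROIDataset,
    cfg: MethodConfig,
    counts: list[int],
    k: int,
    seed: int,
) -> tuple[dict[int, list[ConfusionCounts]], Any]:
    y = dataset.labels
    if np.unique(y).size != 2:
        raise ValueError("cross-validation requires binary labels")
    positive = _positive_class(y)
    c_max = max(counts)
    folds = stratified_kfold(y, k, seed)
    per_count: dict[int, list[ConfusionCounts]] = {c: [] for c in counts}
    for f in range(k):
        train = dataset.subset(folds != f)
        test = dataset.subset(folds == f)
        fold_seed = (seed * 9973 + f) % (2 ** 31)
        try:
            Ftr, Fte, _ = _fold_features(train, test, cfg, c_max,
                                         fold_seed, positive)
        except ValueError as exc:
            raise ValueError(f"fold {f}: {exc}") from exc
        for c in counts:
            sub_tr = FeatureMatrix(coeffs=Ftr[:c], labels=train.labels)
            model = lda_fit(sub_tr, positive_class=positive)
            pred = lda_predict(
                model, FeatureMatrix(coeffs=Fte[:c], labels=test.labels)
            )
            per_count[c].append(_confusion(test.labels, pred, positive))
    return per_count, positive


def _mean(vals: list[float | None]) -> float | None:
    vals = [v for v in vals if v is not None]
    return float(np.mean(vals)) if vals else None


def crossvalidate(
    dataset: ROIDataset,
    method: MethodConfig | str,
    n_components: int,
    k: int = 10,
    seed: int = 0,
) -> EvalReport:
    """k-fold stratified CV of one pipeline configuration.

    Every sample lands in exactly one test fold; all fitting sees only
    the training folds.  Metric means are unweighted fold averages.
    """
    cfg = MethodConfig(method=method) if isinstance(method, str) else method
    per_count, positive = _run_folds(dataset, cfg, [n_components], k, seed)
    fold_counts = per_count[n_components]
    per_fold = []
    for f, c in enumerate(fold_counts):
        per_fold.append({"fold": f, "counts": asdict(c),
                         "metrics": compute_metrics(c)})
    metrics = [compute_metrics(c) for c in fold_counts]
    return EvalReport(
        per_fold=per_fold,
        mean_accuracy=_mean([m["accuracy"] for m in metrics]),
        mean_sensitivity=_mean([m["sensitivity"] for m in metrics]),
        mean_specificity=_mean([m["specificity"] for m in metrics]),
        config={"method": cfg.method, "n_components": n_components,
                "k": k, "seed": seed, "criterion": cfg.criterion,
                "positive_class": positive},
    )


def component_sweep(
    dataset: ROIDataset,
    method: MethodConfig | str,
    component_range,
    k: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean CV metrics for every component count in ``component_range``.

    Returns a tidy table with columns (method, n_components, accuracy,
    sensitivity, specificity), one row per requested count.
    """
    cfg = MethodConfig(method=method) if isinstance(method, str) else method
    counts = sorted(set(int(c) for c in component_range))
    if not counts or counts[0] < 1:
        raise ValueError("component_range must contain positive counts")
    per_count, _ = _run_folds(dataset, cfg, counts, k, seed)
    rows = []
    for c in counts:
        metrics = [compute_metrics(cc) for cc in per_count[c]]
        rows.append({
            "method": cfg.method,
            "n_components": c,
            "accuracy": _mean([m["accuracy"] for m in metrics]),
            "sensitivity": _mean([m["sensitivity"] for m in metrics]),
            "specificity": _mean([m["specificity"] for m in metrics]),
        })
    return pd.DataFrame(rows)
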