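"""Greedy pursuit-style basis selection wrapped around the LDA classifier.

Starting from an empty subspace, each step tries every remaining
candidate basis, refits the discriminant on the training coefficients
of the grown subspace, scores it on the training set, and keeps the
candidate with the best score; ties go to the lowest candidate index.
The selected order is prefix-consistent: the first c indices of a
length-d selection are exactly the length-c selection, which the
component sweep exploits.

Applied to ICA filters and Gabor banks; PCA components are instead
taken in variance order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import BasisSet, FeatureMatrix, ROIDataset
from .lda import lda_fit, lda_predict

__all__ = ["SelectionResult", "greedy_select", "select_bases"]


@dataclass
class SelectionResult:
    """Ordered candidate indices plus the training score at each step."""

    selected_indices: list[int]
    step_scores: list[float]
    criterion: str

    def __post_init__(self) -> None:
        if len(self.selected_indices) != len(set(self.selected_indices)):
            raise ValueError("selected indices must be unique")
        if len(self.step_scores) != len(self.selected_indices):
            raise ValueError("one step score per selected index required")


def _score(y_true: np.ndarray, y_pred: np.ndarray, criterion: str,
           positive) -> float:
    if criterion == "accuracy":
        return float(np.mean(y_true == y_pred))
    pos = y_true == positive
    if criterion == "sensitivity":
        return float(np.mean(y_pred[pos] == positive)) if pos.any() else 0.0
    if criterion == "specificity":
        neg = ~pos
        return float(np.mean(y_pred[neg] != positive)) if neg.any() else 0.0
    raise ValueError(f"unknown selection criterion {criterion!r}")


def greedy_select(
    features: FeatureMatrix,
    n_select: int,
    criterion: str = "accuracy",
    positive_class=None,
) -> SelectionResult:
    """Forward selection over the rows of a candidate feature matrix.

    ``features`` holds the training coefficients of ALL candidate bases
    (one row per candidate); the subspace grows by the row whose
    addition maximizes the training-set ``criterion`` under a freshly
    fitted LDA.  Deterministic: ties break to the lowest index.
    """
    F = features.coeffs
    y = features.labels
    n_cand = F.shape[0]
    if not (1 <= n_select <= n_cand):
        raise ValueError(f"n_select={n_select} out of range [1, {n_cand}]")
    if np.unique(y).size < 2:
        raise ValueError("selection requires at least 2 classes")

    selected: list[int] = []
    scores: list[float] = []
    remaining = list(range(n_cand))
    for _ in range(n_select):
        best_j = None
        best_s = -np.inf
        for j in remaining:  # ascending order + strict '>' = lowest-index ties
            idx = selected + [j]
            try:
                sub = FeatureMatrix(coeffs=F[idx], labels=y)
                model = lda_fit(sub, positive_class=positive_class)
                s = _score(y, lda_predict(model, sub), criterion,
                           model.positive_class)
            except ValueError:
                s = -np.inf  # degenerate subspace: never preferred
            if s > best_s:
                best_s, best_j = s, j
        selected.append(best_j)
        scores.append(best_s)
        remaining.remove(best_j)
    return SelectionResult(selected_indices=selected, step_scores=scores,
                           criterion=criterion)


def select_bases(
    candidates: BasisSet,
    train: ROIDataset,
    n_select: int,
    criterion: str = "accuracy",
    positive_class=None,
) -> SelectionResult:
    """Greedy selection directly from a BasisSet.

    Candidate coefficients are inner products of the train-mean-centered
    sample vectors with each basis column; labels come from the training
    dataset.  ``selection_rank`` is written into the basis metadata.
    """
    if train.dim != candidates.vectors.shape[0]:
        raise ValueError("basis length does not match data dimension")
    Xc = train.data - train.data.mean(axis=1, keepdims=True)
    feats = FeatureMatrix(coeffs=candidates.vectors.T @ Xc, labels=train.labels)
    result = greedy_select(feats, n_select, criterion=criterion,
                           positive_class=positive_class)
    for rank, idx in enumerate(result.selected_indices):
        candidates.meta[idx]["selection_rank"] = rank
    return result
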