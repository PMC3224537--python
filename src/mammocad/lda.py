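"""Fisher linear discriminant built from between/within scatter matrices.

For two classes with sizes n_i, means x_i and grand mean x, the
between-group scatter is B = sum_i n_i (x_i - x)(x_i - x)^T and the
within-group scatter W is the pooled sum of squared deviations around
the class means (n_i-weighted pooling of the class covariances).  The
discriminant direction beta maximizes the Rayleigh ratio
(beta^T B beta)/(beta^T W beta), i.e. it is the top eigenvector of
W^-1 B; samples are classified by thresholding beta^T x at the midpoint
of the projected class means (equal priors).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any

import numpy as np
import scipy.linalg

from .datatypes import FeatureMatrix

__all__ = ["LDAModel", "lda_fit", "lda_predict", "fisher_ratio"]

#: Relative ridge added to a singular within-class scatter.
_RIDGE = 1e-6


@dataclass
class LDAModel:
    beta: np.ndarray
    between_scatter: np.ndarray
    within_scatter: np.ndarray
    class_means: dict[Any, np.ndarray]
    grand_mean: np.ndarray
    threshold: float
    positive_class: Any
    negative_class: Any


def _default_positive(classes: list) -> Any:
    """'mass'/'malignant' if present (the disease class), else the last
    label in sorted order."""
    for preferred in ("mass", "malignant"):
        if preferred in classes:
            return preferred
    return classes[-1]


def lda_fit(
    features: FeatureMatrix,
    labels=None,
    positive_class: Any | None = None,
) -> LDAModel:
    """Fit the two-class Fisher discriminant.

    beta is unit-norm and oriented so the positive class has the larger
    projected mean; the decision threshold is the midpoint of the two
    projected class means.  A singular within scatter is ridge-
    regularized (lambda = 1e-6 * trace(W)/p) instead of failing, so the
    greedy selection loop can probe near-degenerate subspaces.
    """
    F = features.coeffs
    y = np.asarray(features.labels if labels is None else labels)
    if y.shape[0] != F.shape[1]:
        raise ValueError("label count must match feature columns")
    classes = sorted(np.unique(y).tolist())
    if len(classes) != 2:
        raise ValueError(f"Fisher LDA requires exactly 2 classes, got {classes}")
    for cls in classes:
        if np.count_nonzero(y == cls) < 2:
            raise ValueError(f"class {cls!r} needs at least 2 samples")
    if positive_class is None:
        positive_class = _default_positive(classes)
    elif positive_class not in classes:
        raise ValueError(f"positive_class {positive_class!r} not in labels")
    negative_class = [c for c in classes if c != positive_class][0]

    p = F.shape[0]
    grand_mean = F.mean(axis=1)
    B = np.zeros((p, p))
    W = np.zeros((p, p))
    class_means: dict[Any, np.ndarray] = {}
    for cls in classes:
        Fc = F[:, y == cls]
        mi = Fc.mean(axis=1)
        class_means[cls] = mi
        d = mi - grand_mean
        B += Fc.shape[1] * np.outer(d, d)
        R = Fc - mi[:, None]
        W += R @ R.T

    Wr = W
    vals = np.linalg.eigvalsh(W)
    if vals[0] <= 1e-12 * max(vals[-1], 1.0):
        lam = _RIDGE * max(np.trace(W) / p, 1.0)
        Wr = W + lam * np.eye(p)
    try:
        eigvals, eigvecs = scipy.linalg.eigh(B, Wr)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise ValueError("degenerate within-class scatter") from exc
    beta = eigvecs[:, -1]
    beta = beta / np.linalg.norm(beta)

    mu_pos = float(beta @ class_means[positive_class])
    mu_neg = float(beta @ class_means[negative_class])
    if mu_pos < mu_neg:
        beta = -beta
        mu_pos, mu_neg = -mu_pos, -mu_neg
    threshold = 0.5 * (mu_pos + mu_neg)
    return LDAModel(beta=beta, between_scatter=B, within_scatter=W,
                    class_means=class_means, grand_mean=grand_mean,
                    threshold=threshold, positive_class=positive_class,
                    negative_class=negative_class)


def lda_predict(model: LDAModel, features: FeatureMatrix) -> np.ndarray:
    """Labels via the Fisher rule: positive iff beta^T x > threshold.

    Scores exactly at the threshold go to the negative (non-mass)
    class.
    """
    F = features.coeffs
    if F.shape[0] != model.beta.shape[0]:
        raise ValueError(
            f"feature dimension {F.shape[0]} does not match model "
            f"{model.beta.shape[0]}"
        )
    scores = model.beta @ F
    out = np.where(scores > model.threshold,
                   model.positive_class, model.negative_class)
    return out


def fisher_ratio(direction: np.ndarray, model: LDAModel) -> float:
    """Rayleigh quotient (d^T B d)/(d^T W d); scale-invariant in d."""
    d = np.asarray(direction, dtype=np.float64).ravel()
    if not np.any(d):
        raise ValueError("direction must be nonzero")
    num = float(d @ model.between_scatter @ d)
    den = float(d @ model.within_scatter @ d)
    if den == 0:
        return np.inf if num > 0 else 0.0
    return num / den
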