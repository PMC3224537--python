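"""PCA eigenimage basis: fit on training vectors, project onto top-k axes.

The basis is learned by eigendecomposing the sample covariance of the
mean-centered training columns (1/(n-1) normalization) and sorting the
eigenpairs by decreasing variance.  Components for classification are
taken in variance order; no wrapper selection is applied to PCA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import FeatureMatrix, ROIDataset

__all__ = ["PCABasis", "pca_fit", "pca_project"]


@dataclass
class PCABasis:
    """Mean vector mu, orthonormal component matrix V (one eigenimage per
    column), and the matching eigenvalues in non-increasing order."""

    mean: np.ndarray
    components: np.ndarray
    eigenvalues: np.ndarray

    @property
    def n_components(self) -> int:
        return self.components.shape[1]


def _fix_signs(components: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: largest-|entry| of each column > 0."""
    idx = np.argmax(np.abs(components), axis=0)
    signs = np.sign(components[idx, np.arange(components.shape[1])])
    signs[signs == 0] = 1.0
    return components * signs


def pca_fit(data: ROIDataset) -> PCABasis:
    """Learn the eigenimage basis from a training dataset.

    Implemented through the thin SVD of the centered data matrix, which
    yields the covariance eigenpairs (eigenvalue = s^2/(n-1)) without
    forming the p x p covariance explicitly; at most min(p, n)
    components are returned, already sorted by decreasing variance.
    """
    X = data.data
    n = X.shape[1]
    if n < 2:
        raise ValueError("PCA requires at least 2 samples")
    mean = X.mean(axis=1)
    Xc = X - mean[:, None]
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    eigenvalues = (s ** 2) / (n - 1)
    components = _fix_signs(U)
    return PCABasis(mean=mean, components=components, eigenvalues=eigenvalues)


def pca_project(data: ROIDataset, basis: PCABasis, k: int) -> FeatureMatrix:
    """Coefficients of each sample on the first k principal axes.

    Columns are centered with the TRAINING mean stored in the basis, so
    projecting held-out data leaks no test-set statistics.
    """
    if not (1 <= k <= basis.n_components):
        raise ValueError(
            f"k={k} out of range [1, {basis.n_components}]"
        )
    if data.dim != basis.mean.shape[0]:
        raise ValueError(
            f"data dimension {data.dim} does not match basis "
            f"{basis.mean.shape[0]}"
        )
    Xc = data.data - basis.mean[:, None]
    coeffs = basis.components[:, :k].T @ Xc
    return FeatureMatrix(coeffs=coeffs, labels=data.labels,
                         basis_indices=list(range(k)))
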