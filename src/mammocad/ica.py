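"""Efficient coding of ROI patches with a fixed-point FastICA estimator.

The model is x = A s with statistically independent coefficients s and
basis images in the columns of A; the filters W = A^-1 recover s = W x.
After whitening, each unit vector w_i is driven to maximize the
non-Gaussianity of the projection w_i^T z, measured by an approximation
of negentropy

    J(u) ~ (E[G(u)] - E[G(nu)])^2,   nu ~ N(0, 1),

with an even, nonquadratic contrast G (log-cosh by default).  The
fixed-point update

    w <- E[z g(w^T z)] - E[g'(w^T z)] w

is applied to all rows in parallel with symmetric decorrelation each
sweep, which makes the fit order-independent and reproducible under a
fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datatypes import FeatureMatrix, ROIDataset

__all__ = [
    "WhitenModel",
    "ICAModel",
    "whiten",
    "negentropy_approx",
    "fastica_fit",
    "fit_efficient_coding",
    "ica_project",
    "amari_index",
]


# ---------------------------------------------------------------------------
# Contrast functions: G, g = G', g' = G''
# ---------------------------------------------------------------------------

def _logcosh(u):
    return np.log(np.cosh(u))


def _g_logcosh(u):
    return np.tanh(u)


def _dg_logcosh(u):
    t = np.tanh(u)
    return 1.0 - t * t


def _exp(u):
    return -np.exp(-0.5 * u * u)


def _g_exp(u):
    return u * np.exp(-0.5 * u * u)


def _dg_exp(u):
    e = np.exp(-0.5 * u * u)
    return (1.0 - u * u) * e


def _cube(u):
    return 0.25 * u ** 4


def _g_cube(u):
    return u ** 3


def _dg_cube(u):
    return 3.0 * u * u


_CONTRASTS = {
    "logcosh": (_logcosh, _g_logcosh, _dg_logcosh),
    "exp": (_exp, _g_exp, _dg_exp),
    "cube": (_cube, _g_cube, _dg_cube),
}

_GAUSS_EG: dict[str, float] = {}


def _gauss_expectation(contrast: str) -> float:
    """E[G(nu)] for standard normal nu, via Gauss-Hermite quadrature."""
    if contrast not in _GAUSS_EG:
        G = _CONTRASTS[contrast][0]
        nodes, weights = np.polynomial.hermite_e.hermegauss(201)
        _GAUSS_EG[contrast] = float(weights @ G(nodes) / np.sqrt(2 * np.pi))
    return _GAUSS_EG[contrast]


# ---------------------------------------------------------------------------
# Whitening
# ---------------------------------------------------------------------------

@dataclass
class WhitenModel:
    """Centering + sphering transform learned from training data.

    ``whitening`` maps centered data to unit-covariance coordinates
    (rank x p); ``dewhitening`` (p x rank) is its pseudo-inverse.
    """

    mean: np.ndarray
    whitening: np.ndarray
    dewhitening: np.ndarray
    retained_rank: int
    eigenvalues: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        return self.whitening @ (X - self.mean[:, None])


def whiten(
    data: ROIDataset | np.ndarray,
    var_floor: float = 1e-10,
    n_components: int | None = None,
) -> tuple[np.ndarray, WhitenModel]:
    """Center and sphere the data columns.

    Principal directions with variance below var_floor times the top
    variance are dropped; ``n_components`` optionally caps the retained
    rank further.  Returns (whitened data, model).
    """
    X = data.data if isinstance(data, ROIDataset) else np.asarray(data, float)
    n = X.shape[1]
    if n < 2:
        raise ValueError("whitening requires at least 2 samples")
    mean = X.mean(axis=1)
    Xc = X - mean[:, None]
    if not np.any(Xc):
        raise ValueError("cannot whiten all-zero (constant) data")
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    lam = (s ** 2) / (n - 1)
    keep = lam > var_floor * lam[0]
    rank = int(np.count_nonzero(keep))
    if n_components is not None:
        rank = min(rank, n_components)
    U = U[:, :rank]
    lam = lam[:rank]
    whitening = (U / np.sqrt(lam)).T          # rank x p
    dewhitening = U * np.sqrt(lam)            # p x rank
    model = WhitenModel(mean=mean, whitening=whitening,
                        dewhitening=dewhitening, retained_rank=rank,
                        eigenvalues=lam)
    return whitening @ Xc, model


# ---------------------------------------------------------------------------
# Negentropy approximation
# ---------------------------------------------------------------------------

def negentropy_approx(coeffs: np.ndarray, contrast: str = "logcosh") -> float:
    """Non-Gaussianity score J of a 1-D sample; zero for Gaussian data.

    The sample is standardized to zero mean and unit variance first, so
    the score depends only on shape.  G even implies sign symmetry.
    """
    u = np.asarray(coeffs, dtype=np.float64).ravel()
    if u.size < 2:
        raise ValueError("need at least 2 values")
    sd = u.std()
    if sd == 0:
        raise ValueError("zero-variance sample has undefined negentropy")
    u = (u - u.mean()) / sd
    if contrast not in _CONTRASTS:
        raise ValueError(f"unknown contrast {contrast!r}")
    G = _CONTRASTS[contrast][0]
    return float((G(u).mean() - _gauss_expectation(contrast)) ** 2)


# ---------------------------------------------------------------------------
# FastICA
# ---------------------------------------------------------------------------

@dataclass
class ICAModel:
    """Fitted efficient-coding model.

    ``filters_white`` are the orthonormal unmixing rows in whitened
    coordinates; ``filters`` act on centered input-space data
    (s = filters @ (x - mean)); ``basis`` holds the input-space basis
    images a_i as columns, with filters @ basis = I on the retained
    subspace.
    """

    filters_white: np.ndarray
    filters: np.ndarray
    basis: np.ndarray
    whiten: WhitenModel
    converged: bool
    convergence_log: list[float] = field(default_factory=list)
    n_iter: int = 0

    @property
    def n_components(self) -> int:
        return self.filters_white.shape[0]


def _sym_decorrelate(W: np.ndarray) -> np.ndarray:
    """W <- (W W^T)^(-1/2) W via eigendecomposition."""
    vals, vecs = np.linalg.eigh(W @ W.T)
    vals = np.clip(vals, 1e-12, None)
    return (vecs / np.sqrt(vals)) @ vecs.T @ W


def fastica_fit(
    z: np.ndarray,
    whiten_model: WhitenModel,
    n_components: int | None = None,
    *,
    contrast: str = "logcosh",
    max_iter: int = 200,
    tol: float = 1e-4,
    seed: int = 0,
) -> ICAModel:
    """Parallel fixed-point FastICA on whitened data ``z`` (rank x n).

    Convergence is declared when the largest per-row angle change,
    measured as 1 - |cos|, falls below ``tol``.  A non-converged fit is
    returned flagged, never raised: on Gaussian data independent
    directions are unidentifiable and the caller decides.
    """
    z = np.asarray(z, dtype=np.float64)
    rank, n = z.shape
    c = rank if n_components is None else n_components
    if not (1 <= c <= rank):
        raise ValueError(f"n_components={c} exceeds retained rank {rank}")
    if contrast not in _CONTRASTS:
        raise ValueError(f"unknown contrast {contrast!r}")
    _, g, dg = _CONTRASTS[contrast]
    rng = np.random.default_rng(seed)
    W = _sym_decorrelate(rng.standard_normal((c, rank)))
    log: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        wz = W @ z
        gwz = g(wz)
        W_new = (gwz @ z.T) / n - np.mean(dg(wz), axis=1)[:, None] * W
        W_new = _sym_decorrelate(W_new)
        delta = float(np.max(1.0 - np.abs(np.einsum("ij,ij->i", W_new, W))))
        log.append(delta)
        W = W_new
        if delta < tol:
            converged = True
            break
    filters = W @ whiten_model.whitening
    basis = whiten_model.dewhitening @ W.T
    return ICAModel(filters_white=W, filters=filters, basis=basis,
                    whiten=whiten_model, converged=converged,
                    convergence_log=log, n_iter=it)


def fit_efficient_coding(
    data: ROIDataset,
    n_components: int | None = None,
    var_floor: float = 1e-10,
    **opts,
) -> ICAModel:
    """Whiten a training dataset and fit FastICA in one call."""
    z, wm = whiten(data, var_floor=var_floor, n_components=n_components)
    return fastica_fit(z, wm, n_components=None, **opts)


def ica_project(
    data: ROIDataset,
    model: ICAModel,
    selected: list[int] | None = None,
) -> FeatureMatrix:
    """Coefficients s of each sample w.r.t. the selected filters.

    Rows follow the order of ``selected`` (all filters if None).
    """
    if selected is None:
        selected = list(range(model.n_components))
    sel = np.asarray(selected, dtype=int)
    if sel.size and (sel.min() < 0 or sel.max() >= model.n_components):
        raise IndexError(
            f"filter index out of range [0, {model.n_components})"
        )
    if data.dim != model.whiten.mean.shape[0]:
        raise ValueError("data dimension does not match model")
    Xc = data.data - model.whiten.mean[:, None]
    coeffs = model.filters[sel] @ Xc
    return FeatureMatrix(coeffs=coeffs, labels=data.labels,
                         basis_indices=sel.tolist())


# ---------------------------------------------------------------------------
# Evaluation helper
# ---------------------------------------------------------------------------

def amari_index(P: np.ndarray) -> float:
    """Permutation/scale-invariant distance of P = W_est @ A_true from a
    scaled permutation matrix; 0 means perfect source recovery, values
    near 1 mean no recovery.  Standard normalized form."""
    P = np.abs(np.asarray(P, dtype=np.float64))
    n = P.shape[0]
    if P.shape[0] != P.shape[1]:
        raise ValueError("Amari index requires a square matrix")
    rows = (P / P.max(axis=1, keepdims=True)).sum(axis=1) - 1.0
    cols = (P / P.max(axis=0, keepdims=True)).sum(axis=0) - 1.0
    return float((rows.sum() + cols.sum()) / (2.0 * n * (n - 1)))
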