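"""Multi-scale, multi-orientation Gabor filter bank on the ROI grid.

The mother wavelet is the canonical Gaussian-envelope complex sinusoid

    g(x, y) = exp(-0.5 (x^2/sx^2 + y^2/sy^2)) * exp(2*pi*j*F*x),

and bank member (m, n) is g evaluated on coordinates rotated by
theta = n*pi/k and shrunk by a^(m-1), so its carrier frequency is
F * a^-(m-1); m = 1..M scales, n = 0..k-1 orientations.  Only the real
part is kept.  Every emitted kernel is rendered on the centered
grid_side x grid_side grid, DC-corrected to exactly zero mean and
L2-normalized, so projections are insensitive to additive intensity
offsets.

Features are plain inner products of sample vectors with filter
vectors (one coefficient per filter), in parallel with the PCA/ICA
projections; no convolution or pooling is involved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import BasisSet, FeatureMatrix, ROIDataset

__all__ = ["GaborParams", "gabor_kernel", "gabor_bank", "gabor_project"]

#: Lowest carrier frequency the default bank tiles down to (cycles/pixel).
_DEFAULT_LOW_FREQ = 0.05


@dataclass(frozen=True)
class GaborParams:
    """Bank geometry.

    base_frequency is the carrier at scale m = 1, in cycles/pixel;
    scale_factor is the ratio between successive scales (None derives
    it so the M scales tile from base_frequency down to 0.05
    cycles/pixel); sigma_x/sigma_y set the envelope of the mother
    wavelet in pixels (~1 octave bandwidth at the default).
    """

    n_scales: int = 10
    n_orientations: int = 10
    base_frequency: float = 0.4
    scale_factor: float | None = None
    sigma_x: float = 1.5
    sigma_y: float = 1.5
    grid_side: int = 32

    def __post_init__(self) -> None:
        if self.n_scales < 1 or self.n_orientations < 1:
            raise ValueError("need at least 1 scale and 1 orientation")
        if self.base_frequency <= 0:
            raise ValueError("base_frequency must be positive")
        if self.grid_side < 2:
            raise ValueError("grid_side must be >= 2")

    @property
    def a(self) -> float:
        """Scale ratio between successive bank levels."""
        if self.scale_factor is not None:
            return self.scale_factor
        if self.n_scales == 1:
            return 1.0
        return (self.base_frequency / _DEFAULT_LOW_FREQ) ** (
            1.0 / (self.n_scales - 1)
        )


def _kernel_at_angle(m: int, theta: float, params: GaborParams) -> np.ndarray:
    """Raw real Gabor kernel at scale index m and carrier angle theta."""
    side = params.grid_side
    c = (side - 1) / 2.0
    yy, xx = np.mgrid[0:side, 0:side]
    x = xx - c
    y = yy - c
    scale = params.a ** (-(m - 1))
    xr = scale * (x * np.cos(theta) + y * np.sin(theta))
    yr = scale * (-x * np.sin(theta) + y * np.cos(theta))
    envelope = np.exp(
        -0.5 * ((xr / params.sigma_x) ** 2 + (yr / params.sigma_y) ** 2)
    )
    carrier = np.cos(2.0 * np.pi * params.base_frequency * xr)
    return scale * envelope * carrier


def _finalize(kernel: np.ndarray) -> np.ndarray:
    """DC-correct to zero mean and L2-normalize."""
    kernel = kernel - kernel.mean()
    norm = np.linalg.norm(kernel)
    if norm == 0:
        raise ValueError("degenerate Gabor kernel (all-zero after DC removal)")
    return kernel / norm


def gabor_kernel(m: int, n: int, params: GaborParams) -> np.ndarray:
    """Bank member (m, n) rendered on the grid: zero-mean, unit-norm.

    m in 1..n_scales, n in 0..n_orientations-1; orientation
    theta = n*pi/n_orientations (period pi, as the real carrier is even
    under a half-turn).
    """
    if not (1 <= m <= params.n_scales):
        raise ValueError(f"scale index m={m} out of range [1, {params.n_scales}]")
    if not (0 <= n < params.n_orientations):
        raise ValueError(
            f"orientation index n={n} out of range [0, {params.n_orientations})"
        )
    theta = n * np.pi / params.n_orientations
    return _finalize(_kernel_at_angle(m, theta, params))


def gabor_bank(params: GaborParams | None = None) -> BasisSet:
    """All n_scales x n_orientations filters, m outer and n inner,
    vectorized row-major to grid_side**2 columns."""
    params = params or GaborParams()
    cols = []
    meta = []
    for m in range(1, params.n_scales + 1):
        for n in range(params.n_orientations):
            k = gabor_kernel(m, n, params)
            cols.append(k.ravel(order="C"))
            meta.append({
                "kind": "gabor",
                "scale": m,
                "orientation": n,
                "frequency": params.base_frequency * params.a ** (-(m - 1)),
                "theta": n * np.pi / params.n_orientations,
            })
    return BasisSet(vectors=np.column_stack(cols), meta=meta)


def gabor_project(
    data: ROIDataset,
    bank: BasisSet,
    selected: list[int] | None = None,
) -> FeatureMatrix:
    """Inner product of each sample vector with each selected filter.

    Filters are zero-mean, so the coefficients are invariant to any
    per-sample additive offset; rows follow the order of ``selected``.
    """
    if selected is None:
        selected = list(range(bank.n_bases))
    sel = np.asarray(selected, dtype=int)
    if sel.size and (sel.min() < 0 or sel.max() >= bank.n_bases):
        raise IndexError(f"filter index out of range [0, {bank.n_bases})")
    if data.dim != bank.vectors.shape[0]:
        raise ValueError("data dimension does not match filter length")
    coeffs = bank.vectors[:, sel].T @ data.data
    return FeatureMatrix(coeffs=coeffs, labels=data.labels,
                         basis_indices=sel.tolist())
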