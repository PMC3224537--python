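"""Core in-memory containers shared across the pipeline.

The canonical sample representation is a grayscale region of interest
(ROI) patch, histogram-equalized, resized to a square grid (32x32 by
default) and flattened row-major into a vector ``x`` of length
``side**2``.  A dataset stores one such vector per column.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np

__all__ = [
    "ROIImage",
    "ROIDataset",
    "BasisSet",
    "FeatureMatrix",
]


@dataclass
class ROIImage:
    """One grayscale patch with 8-bit intensities.

    Parameters
    ----------
    pixels : ndarray of uint8, shape (h, w)
        Intensity grid; values must lie in [0, 255].
    source_id : str
        Provenance string (filename, synthetic tag, ...).
    """

    pixels: np.ndarray
    source_id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("ROIImage requires a non-empty 2-D pixel grid")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ValueError("ROIImage intensities must lie in [0, 255]")
            px = px.astype(np.uint8)
        self.pixels = px

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class ROIDataset:
    """Column matrix of vectorized ROIs plus aligned labels and ids.

    ``data`` has shape (p, n): one length-p sample vector per column,
    with p = side**2 for the canonical side.
    """

    data: np.ndarray
    labels: np.ndarray
    ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("dataset data must be a 2-D matrix")
        self.labels = np.asarray(self.labels)
        n = self.data.shape[1]
        if self.labels.shape != (n,):
            raise ValueError(
                f"label count {self.labels.shape} does not match {n} columns"
            )
        if not self.ids:
            self.ids = [f"sample-{i}" for i in range(n)]
        if len(self.ids) != n:
            raise ValueError("id count does not match column count")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def dim(self) -> int:
        return self.data.shape[0]

    def class_counts(self) -> dict[Any, int]:
        vals, counts = np.unique(self.labels, return_counts=True)
        return dict(zip(vals.tolist(), counts.tolist()))

    def subset(self, index: np.ndarray) -> "ROIDataset":
        """Column subset (boolean mask or integer index array)."""
        idx = np.asarray(index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return ROIDataset(
            data=self.data[:, idx],
            labels=self.labels[idx],
            ids=[self.ids[i] for i in idx],
        )


@dataclass
class BasisSet:
    """Matrix of basis/filter vectors, one per column, with metadata.

    ``meta`` holds one dict per column, e.g. ``{"kind": "gabor",
    "scale": m, "orientation": n}`` or ``{"kind": "pca",
    "eigenvalue": lam}``; a ``selection_rank`` key is added once a
    greedy selection has ordered the columns.
    """

    vectors: np.ndarray
    meta: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        if self.vectors.ndim != 2:
            raise ValueError("basis vectors must form a 2-D matrix")
        if not self.meta:
            self.meta = [{} for _ in range(self.vectors.shape[1])]
        if len(self.meta) != self.vectors.shape[1]:
            raise ValueError("meta length must match basis column count")

    @property
    def n_bases(self) -> int:
        return self.vectors.shape[1]


@dataclass
class FeatureMatrix:
    """Projection coefficients aligned to labels.

    ``coeffs`` has shape (k, n): one row per basis/filter, one column
    per sample, in the same order as the source dataset.
    """

    coeffs: np.ndarray
    labels: np.ndarray
    basis_indices: Sequence[int] | None = None

    def __post_init__(self) -> None:
        self.coeffs = np.atleast_2d(np.asarray(self.coeffs, dtype=np.float64))
        self.labels = np.asarray(self.labels)
        if self.coeffs.shape[1] != self.labels.shape[0]:
            raise ValueError("feature columns must match label count")

    @property
    def n_features(self) -> int:
        return self.coeffs.shape[0]

    @property
    def n_samples(self) -> int:
        return self.coeffs.shape[1]
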