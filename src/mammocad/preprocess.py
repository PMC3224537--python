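"""ROI preprocessing: histogram equalization, bilinear resize, vectorization.

The canonical pipeline is equalize -> resize to 32x32 -> row-major
flatten, producing the length-1024 sample vectors the extractors
consume.  Equalization runs before resizing.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy.ndimage import map_coordinates

from .datatypes import ROIDataset, ROIImage

__all__ = [
    "equalize_histogram",
    "resize_roi",
    "vectorize",
    "build_dataset",
    "load_roi",
    "save_roi",
    "load_dataset",
    "save_images",
]

CANONICAL_SIDE = 32


def equalize_histogram(image: ROIImage) -> ROIImage:
    """Discrete histogram equalization over 256 intensity levels.

    Each level v is mapped through the empirical CDF rescaled to
    [0, 255]::

        out(v) = round(255 * (cdf(v) - cdf_min) / (N - cdf_min))

    where N is the pixel count and cdf_min the CDF at the lowest
    occupied level.  A constant image (cdf_min == N) is returned
    unchanged.
    """
    px = image.pixels
    hist = np.bincount(px.ravel(), minlength=256)
    cdf = np.cumsum(hist)
    n = px.size
    cdf_min = int(cdf[np.flatnonzero(hist)[0]])
    if cdf_min == n:  # constant image: degenerate CDF
        return ROIImage(px.copy(), image.source_id)
    lut = np.round(255.0 * (cdf - cdf_min) / (n - cdf_min))
    lut = np.clip(lut, 0, 255).astype(np.uint8)
    return ROIImage(lut[px], image.source_id)


def resize_roi(image: ROIImage, side: int = CANONICAL_SIDE) -> ROIImage:
    """Resize to side x side with half-pixel-centered bilinear sampling.

    Output pixel (i, j) samples the input at
    ((i + 0.5) * h / side - 0.5, (j + 0.5) * w / side - 0.5), edge
    coordinates clamped.  Output intensities stay within the input's
    [min, max] range.
    """
    if side < 2:
        raise ValueError(f"target side must be >= 2, got {side}")
    px = image.pixels
    h, w = px.shape
    if (h, w) == (side, side):
        return ROIImage(px.copy(), image.source_id)
    rows = (np.arange(side) + 0.5) * h / side - 0.5
    cols = (np.arange(side) + 0.5) * w / side - 0.5
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    out = map_coordinates(px.astype(np.float64), [rr, cc], order=1, mode="nearest")
    out = np.clip(np.round(out), px.min(), px.max()).astype(np.uint8)
    return ROIImage(out, image.source_id)


def vectorize(image: ROIImage) -> np.ndarray:
    """Row-major concatenation of pixel rows into the sample vector x."""
    return image.pixels.astype(np.float64).ravel(order="C")


def build_dataset(
    images: list[ROIImage],
    labels,
    side: int = CANONICAL_SIDE,
) -> ROIDataset:
    """Equalize, resize and vectorize each image; assemble the column matrix.

    Order is preserved; column i is vectorize(resize(equalize(images[i]))).
    """
    labels = list(labels)
    if len(images) != len(labels):
        raise ValueError(
            f"{len(images)} images but {len(labels)} labels"
        )
    if not images:
        raise ValueError("cannot build a dataset from zero images")
    cols = []
    ids = []
    for img in images:
        proc = resize_roi(equalize_histogram(img), side)
        cols.append(vectorize(proc))
        ids.append(img.source_id)
    data = np.column_stack(cols)
    return ROIDataset(data=data, labels=np.asarray(labels), ids=ids)


# ---------------------------------------------------------------------------
# Disk I/O: PNG/PGM/TIFF images + CSV manifest (filename,label)
# ---------------------------------------------------------------------------

def load_roi(path: str | os.PathLike, source_id: str | None = None) -> ROIImage:
    """Read a grayscale raster image (PNG/PGM/TIFF) as an ROIImage."""
    path = Path(path)
    with Image.open(path) as im:
        px = np.asarray(im.convert("L"), dtype=np.uint8)
    return ROIImage(px, source_id or path.name)


def save_roi(image: ROIImage, path: str | os.PathLike) -> None:
    Image.fromarray(image.pixels, mode="L").save(path)


def save_images(
    images: list[ROIImage],
    labels,
    directory: str | os.PathLike,
    manifest_name: str = "manifest.csv",
) -> Path:
    """Write PNGs plus a CSV manifest (filename,label); returns manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, (img, lab) in enumerate(zip(images, labels)):
        fname = f"roi_{i:05d}.png"
        save_roi(img, directory / fname)
        rows.append({"filename": fname, "label": lab})
    manifest = directory / manifest_name
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def load_dataset(
    manifest: str | os.PathLike,
    side: int = CANONICAL_SIDE,
) -> ROIDataset:
    """Load images listed in a CSV manifest and build the canonical dataset."""
    manifest = Path(manifest)
    table = pd.read_csv(manifest)
    if not {"filename", "label"} <= set(table.columns):
        raise ValueError("manifest must have 'filename' and 'label' columns")
    root = manifest.parent
    images = [load_roi(root / f) for f in table["filename"]]
    return build_dataset(images, table["label"].tolist(), side=side)
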