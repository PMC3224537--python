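"""Synthetic ROI generator: textured non-mass patches vs blob-bearing masses.

Real screen-film mammogram patches are not bundled; this module emulates
the statistical structure the pipeline assumes.  Non-mass patches are a
stationary correlated-noise texture (a Gaussian random field obtained by
smoothing white noise).  Mass patches add a bright, roughly Gaussian
blob; malignant masses get an irregular (spiculated) contour and extra
contrast variance, mirroring the margin/shape descriptors radiologists
use, without any claim of pixel-level realism.

All intensities are clipped to [0, 255] and stored as 8-bit, matching
the digitized-film convention the downstream equalization expects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .datatypes import ROIDataset, ROIImage
from .preprocess import build_dataset

__all__ = ["SynthParams", "generate_roi", "generate_images", "generate_dataset"]

#: Background mean intensity of the texture field (8-bit units).
BASE_INTENSITY = 100.0
#: Standard deviation of the correlated texture component.
TEXTURE_SD = 30.0
#: Blob peak amplitude per unit of blob_contrast, in multiples of
#: TEXTURE_SD.  Calibrated so blob_contrast ~ 1.5 gives nearly separable
#: classes after equalization and ~0.3 is close to chance.
BLOB_GAIN = 2.5

MASS_LABELS = frozenset({"mass", "benign", "malignant"})
NONMASS_LABELS = frozenset({"non-mass"})


@dataclass(frozen=True)
class SynthParams:
    """Knobs of the synthetic ROI distribution.

    blob_contrast is the blob's peak amplitude in units of TEXTURE_SD;
    0 makes mass and non-mass distributions identical.  Correlation
    length and radii are in pixels, noise_sd in intensity units.
    malignant_spiculation in [0, 1] controls contour irregularity of
    malignant masses (benign masses always use 0).
    """

    image_size: int = 32
    blob_contrast: float = 0.8
    blob_radius_range: tuple[float, float] = (6.0, 8.0)
    texture_correlation_length: float = 1.5
    noise_sd: float = 10.0
    malignant_spiculation: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_size < 4:
            raise ValueError("image_size must be >= 4")
        if self.blob_contrast < 0:
            raise ValueError("blob_contrast must be >= 0")
        lo, hi = self.blob_radius_range
        if not (0 < lo <= hi):
            raise ValueError("blob_radius_range must satisfy 0 < lo <= hi")
        if not (0 <= self.malignant_spiculation <= 1):
            raise ValueError("malignant_spiculation must lie in [0, 1]")


def _texture(params: SynthParams, rng: np.random.Generator) -> np.ndarray:
    """Stationary correlated texture + white pixel noise, float64."""
    s = params.image_size
    white = rng.standard_normal((s, s))
    field = gaussian_filter(white, sigma=params.texture_correlation_length,
                            mode="reflect")
    sd = field.std()
    if sd > 0:
        field = field / sd
    img = BASE_INTENSITY + TEXTURE_SD * field
    if params.noise_sd > 0:
        img = img + params.noise_sd * rng.standard_normal((s, s))
    return img


def _blob(params: SynthParams, rng: np.random.Generator,
          spiculation: float, contrast_jitter: bool) -> np.ndarray:
    """Additive bright blob, optionally with a spiculated contour.

    spiculation > 0 (malignant) irregularizes the contour with random
    angular harmonics and also enlarges and sharpens the profile, the
    mean-level shape signature a linear discriminant can latch onto;
    contrast_jitter widens the malignant amplitude spread.
    """
    s = params.image_size
    cy, cx = s / 2.0 + rng.uniform(-0.05 * s, 0.05 * s, size=2)
    radius = rng.uniform(*params.blob_radius_range)
    amp = params.blob_contrast * BLOB_GAIN * TEXTURE_SD
    if contrast_jitter:
        # malignant masses show a wider contrast spread
        amp = amp * np.exp(0.4 * spiculation * rng.standard_normal())
    yy, xx = np.mgrid[0:s, 0:s]
    dy, dx = yy - cy, xx - cx
    dist = np.hypot(dy, dx)
    power = 2.0
    if spiculation > 0:
        radius = radius * (1.0 + 0.4 * spiculation)   # size lift
        power = 2.0 + 2.0 * spiculation               # sharper margin
        # contour irregularity: angular modulation of the radius
        phi = np.arctan2(dy, dx)
        harmonics = np.arange(3, 7)
        coefs = rng.uniform(-1.0, 1.0, size=harmonics.size)
        phases = rng.uniform(0, 2 * np.pi, size=harmonics.size)
        mod = np.zeros_like(phi)
        for h, c, p in zip(harmonics, coefs, phases):
            mod += c * np.cos(h * phi + p)
        local_r = radius * np.clip(1.0 + 0.35 * spiculation * mod, 0.25, None)
    else:
        local_r = radius
    return amp * np.exp(-((dist / local_r) ** power))


def generate_roi(
    label: str,
    params: SynthParams,
    rng: np.random.Generator | None = None,
    source_id: str = "",
) -> ROIImage:
    """Draw one labeled synthetic ROI.

    'non-mass' is texture only; 'mass' and 'benign' add a smooth blob;
    'malignant' adds a spiculated blob with jittered contrast.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    if label in NONMASS_LABELS:
        img = _texture(params, rng)
    elif label in MASS_LABELS:
        spic = params.malignant_spiculation if label == "malignant" else 0.0
        img = _texture(params, rng) + _blob(
            params, rng, spiculation=spic, contrast_jitter=(label == "malignant")
        )
    else:
        raise ValueError(f"unknown ROI label {label!r}")
    px = np.clip(np.round(img), 0, 255).astype(np.uint8)
    return ROIImage(px, source_id or f"synth-{label}")


def generate_images(
    n_per_class: dict[str, int],
    params: SynthParams,
) -> tuple[list[ROIImage], list[str]]:
    """Raw labeled synthetic ROIs, shuffled deterministically by seed."""
    for label, n in n_per_class.items():
        if n < 0:
            raise ValueError(f"negative count {n} for label {label!r}")
        if label not in MASS_LABELS | NONMASS_LABELS:
            raise ValueError(f"unknown ROI label {label!r}")
    rng = np.random.default_rng(params.seed)
    images: list[ROIImage] = []
    labels: list[str] = []
    for label in sorted(n_per_class):
        for i in range(n_per_class[label]):
            images.append(
                generate_roi(label, params, rng,
                             source_id=f"synth-{label}-{i:05d}")
            )
            labels.append(label)
    order = rng.permutation(len(images))
    return [images[i] for i in order], [labels[i] for i in order]


def generate_dataset(
    n_per_class: dict[str, int],
    params: SynthParams,
) -> ROIDataset:
    """Generate, preprocess and assemble a labeled synthetic dataset.

    Columns are the canonical equalized row-major vectors; label counts
    exactly match the request; identical params (incl. seed) reproduce
    the dataset bit for bit.
    """
    images, labels = generate_images(n_per_class, params)
    return build_dataset(images, labels, side=params.image_size)
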