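"""Per-epoch stochastic training augmentation.

Each epoch, a single elastic displacement field is sampled and applied to the
entire training volume (image, labels and loss weights move together), then
random axis reflections and photometric jitter are applied.  The displacement
field is a coarse grid of i.i.d. Gaussian vectors, bilinearly upsampled to the
lateral shape, and the same 2D field displaces every z-slice.

Photometric jitter semantics (the brightness/contrast fractions apply to
z-scored data):

* brightness: additive shift ``gamma_b ~ U(-brightness_frac, +brightness_frac)``
* contrast: scaling about the mean by ``1 + gamma_c``,
  ``gamma_c ~ U(-contrast_frac, +contrast_frac)``

Note on the elastic defaults: the displacement grid is drawn with mean 20 and
standard deviation 0.6 pixels, which produces a near-rigid ~20-pixel
translation plus a small warp.  These defaults are kept literally; a visually
elastic preset is ``AugmentConfig(elastic_mean=0.0, elastic_std=10.0)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume_io import _validate_labels


@dataclass
class AugmentConfig:
    flip_axes: tuple[int, ...] = (0, 1, 2)
    brightness_frac: float = 0.12
    contrast_frac: float = 0.20
    elastic_grid: tuple[int, int] = (20, 20)
    elastic_mean: float = 20.0
    elastic_std: float = 0.6
    enabled: bool = True

    def __post_init__(self) -> None:
        if self.brightness_frac < 0 or self.contrast_frac < 0:
            raise ValueError("jitter fractions must be >= 0")
        if min(self.elastic_grid) < 2:
            raise ValueError("elastic grid dimensions must be >= 2")
        if not set(self.flip_axes) <= {0, 1, 2}:
            raise ValueError("flip_axes must be a subset of {0,1,2}")


def random_flip(
    image: np.ndarray,
    labels: np.ndarray,
    weights: np.ndarray,
    rng: np.random.Generator,
    axes: tuple[int, ...] = (0, 1, 2),
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Independently flip each allowed axis with probability 1/2 (all arrays together)."""
    if not (image.shape == labels.shape == weights.shape):
        raise ValueError("image/labels/weights shapes must match")
    flips = [ax for ax in axes if rng.random() < 0.5]
    if flips:
        image = np.flip(image, axis=flips).copy()
        labels = np.flip(labels, axis=flips).copy()
        weights = np.flip(weights, axis=flips).copy()
    return image, labels, weights


def apply_photometric(image: np.ndarray, gamma_c: float, gamma_b: float) -> np.ndarray:
    """x' = (x - mean(x)) * (1 + gamma_c) + mean(x) + gamma_b."""
    mean = image.mean()
    return ((image - mean) * (1.0 + gamma_c) + mean + gamma_b).astype(image.dtype)


def photometric_jitter(
    image: np.ndarray, rng: np.random.Generator, config: AugmentConfig
) -> np.ndarray:
    """Random brightness/contrast shift; labels and weights are untouched."""
    gamma_c = rng.uniform(-config.contrast_frac, config.contrast_frac)
    gamma_b = rng.uniform(-config.brightness_frac, config.brightness_frac)
    return apply_photometric(image, gamma_c, gamma_b)


def sample_displacement_field(
    lateral_shape: tuple[int, int],
    config: AugmentConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sample a (Y, X, 2) displacement field by bilinear upsampling of a coarse grid.

    The coarse grid is ``elastic_grid + (2,)`` i.i.d. Gaussians with mean
    ``elastic_mean`` and standard deviation ``elastic_std`` per component.
    """
    y, x = lateral_shape
    gy, gx = config.elastic_grid
    if y < gy or x < gx:
        raise ValueError("lateral shape must be at least the elastic grid shape")
    coarse = rng.normal(config.elastic_mean, config.elastic_std, size=(gy, gx, 2))
    yy = np.linspace(0.0, gy - 1.0, y)
    xx = np.linspace(0.0, gx - 1.0, x)
    cy, cx = np.meshgrid(yy, xx, indexing="ij")
    field = np.empty((y, x, 2), dtype=np.float64)
    for comp in range(2):
        field[:, :, comp] = ndimage.map_coordinates(
            coarse[:, :, comp], [cy, cx], order=1, mode="nearest"
        )
    return field


def elastic_deform(
    volume: np.ndarray, field: np.ndarray, interpolation: str = "linear"
) -> np.ndarray:
    """Resample each z-slice at source position ``(y, x) + field(y, x)``.

    Linear interpolation for images and weights, nearest for labels (which
    therefore stay within the input value set).  Out-of-bounds source
    coordinates are reflected.
    """
    if interpolation not in ("linear", "nearest"):
        raise ValueError(f"unknown interpolation {interpolation!r}")
    if np.issubdtype(volume.dtype, np.integer) and interpolation != "nearest":
        raise ValueError("label (integer) arrays must use nearest interpolation")
    z, y, x = volume.shape
    if field.shape != (y, x, 2):
        raise ValueError(
            f"field lateral shape {field.shape[:2]} must match volume {(y, x)}"
        )
    gy, gx = np.meshgrid(np.arange(y), np.arange(x), indexing="ij")
    coords = [gy + field[:, :, 0], gx + field[:, :, 1]]
    order = 1 if interpolation == "linear" else 0
    out = np.empty_like(volume)
    for k in range(z):
        out[k] = ndimage.map_coordinates(
            volume[k], coords, order=order, mode="reflect"
        )
    return out


def augment_epoch(
    image: np.ndarray,
    labels: np.ndarray,
    weights: np.ndarray,
    config: AugmentConfig,
    epoch_rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One epoch's augmentation: elastic deformation, then flips, then jitter.

    A single displacement field deforms the whole volume before the epoch's
    windows are extracted.  Deterministic given ``epoch_rng``.
    """
    if not (image.shape == labels.shape == weights.shape):
        raise ValueError("image/labels/weights shapes must match")
    if not config.enabled:
        return image, labels, weights
    if config.elastic_mean != 0.0 or config.elastic_std != 0.0:
        field = sample_displacement_field(image.shape[1:], config, epoch_rng)
        image = elastic_deform(image, field, "linear")
        labels = elastic_deform(labels, field, "nearest")
        weights = elastic_deform(weights, field, "linear")
    image, labels, weights = random_flip(
        image, labels, weights, epoch_rng, config.flip_axes
    )
    image = photometric_jitter(image, epoch_rng, config)
    _validate_labels(labels)
    return image, labels, weights


#: Identity configuration: no reflections, no jitter, no deformation.
NO_AUGMENT = AugmentConfig(
    flip_axes=(),
    brightness_frac=0.0,
    contrast_frac=0.0,
    elastic_mean=0.0,
    elastic_std=0.0,
    enabled=False,
)
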