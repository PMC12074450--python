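"""The five-image augmented set built from each original image.

Four stochastic-but-seeded transforms in the SimCLR family — crop/resize(+flip),
rotate+translate, grayscale, Gaussian blur — are stacked behind the untouched
original, giving the defense diverse views of one image without ever seeing an
adversarial example. Draws are fixed per (image, seed): the training set is
fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import transform as sktf

from .encoders import JointEncoder

__all__ = ["AugmentedSet", "build_augmented_set", "encode_augmented_set", "N_AUG"]

N_AUG = 5  # original + four transforms

# Transform parameter ranges (SimCLR-style defaults; the source method names
# the four families but not their ranges, so these live here for sweeps).
CROP_AREA_RANGE = (0.6, 1.0)
FLIP_PROB = 0.5
ROT_DEG = 15.0
TRANSLATE_FRAC = 0.10
LUMA = np.array([0.299, 0.587, 0.114])
BLUR_SIGMA = 1.0
BLUR_TRUNCATE = 2.0  # radius 2 at sigma 1 -> 5x5 kernel support

TRANSFORM_LABELS = ["original", "crop_resize_flip", "rotate_translate", "grayscale", "gaussian_blur"]


@dataclass
class AugmentedSet:
    images: list[np.ndarray]  # index 0 is the bit-identical original
    transform_labels: list[str]
    seed: int


def _check_image(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 3 or x.shape[2] != 3:
        raise ValueError(f"expected an (H, W, 3) image, got shape {x.shape}")
    if x.shape[0] < 8 or x.shape[1] < 8:
        raise ValueError("image smaller than 8x8: crop and blur are undefined")
    if x.min() < -1e-9 or x.max() > 1.0 + 1e-9:
        raise ValueError("pixel values must lie in [0, 1]")
    return x


def _crop_resize_flip(x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    H, W, _ = x.shape
    area = rng.uniform(*CROP_AREA_RANGE)
    side = np.sqrt(area)
    hc = max(8, int(round(side * H)))
    wc = max(8, int(round(side * W)))
    top = int(rng.integers(0, H - hc + 1))
    left = int(rng.integers(0, W - wc + 1))
    patch = x[top : top + hc, left : left + wc]
    out = sktf.resize(patch, (H, W), order=1, mode="reflect",
                      anti_aliasing=False, preserve_range=True)
    if rng.uniform() < FLIP_PROB:
        out = out[:, ::-1]
    return np.clip(out, 0.0, 1.0)


def _rotate_translate(x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    H, W, _ = x.shape
    angle = np.deg2rad(rng.uniform(-ROT_DEG, ROT_DEG))
    tx = rng.uniform(-TRANSLATE_FRAC, TRANSLATE_FRAC) * W
    # Rotate about the image center (half-pixel convention), then translate
    # horizontally; reflection padding avoids zero-pixel artifacts that would
    # dominate a linear encoder.
    cy, cx = (H - 1) / 2.0, (W - 1) / 2.0
    center = sktf.AffineTransform(translation=(-cx, -cy))
    rot = sktf.AffineTransform(rotation=angle)
    back = sktf.AffineTransform(translation=(cx + tx, cy))
    tform = center + rot + back
    out = sktf.warp(x, tform.inverse, order=1, mode="reflect", preserve_range=True)
    return np.clip(out, 0.0, 1.0)


def _grayscale(x: np.ndarray) -> np.ndarray:
    lum = x @ LUMA
    return np.repeat(lum[:, :, None], 3, axis=2)


def _blur(x: np.ndarray) -> np.ndarray:
    out = ndimage.gaussian_filter(
        x, sigma=(BLUR_SIGMA, BLUR_SIGMA, 0.0), mode="reflect", truncate=BLUR_TRUNCATE
    )
    return np.clip(out, 0.0, 1.0)


def build_augmented_set(x: np.ndarray, seed: int) -> AugmentedSet:
    """Original plus the four seeded transforms, all in [0, 1], same shape."""
    x = _check_image(x)
    rng = np.random.default_rng(seed)
    images = [
        x.copy(),
        _crop_resize_flip(x, rng),
        _rotate_translate(x, rng),
        _grayscale(x),
        _blur(x),
    ]
    return AugmentedSet(images=images, transform_labels=list(TRANSFORM_LABELS), seed=int(seed))


def encode_augmented_set(encoder: JointEncoder, aug: AugmentedSet) -> np.ndarray:
    """D x N matrix of embeddings; column n encodes images[n], order preserved."""
    cols = [encoder.image_encode(img) for img in aug.images]
    return np.stack(cols, axis=1)
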