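"""Background removal and downsampling for 8-bit grayscale MR images.

The preprocessing chain is: binarize at a normalized threshold (default
0.05, i.e. an 8-bit cut of 12.75), keep the largest connected foreground
component with its interior holes filled, multiply the mask back into the
image, then halve the resolution by 2x2 block averaging.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .errors import DataError, EmptyForegroundError, ValidationError

#: 8-bit intensity cut equivalent to the normalized 0.05 threshold.
BINARIZATION_CUT = 0.05 * (2**8 - 1)  # 12.75

# 8-connectivity for foreground components; holes are filled with the dual
# 4-connected background flood (scipy's default structuring element).
_STRUCT8 = np.ones((3, 3), dtype=bool)


def _as_gray(image) -> np.ndarray:
    arr = np.asarray(image)
    if arr.ndim != 2:
        raise ValidationError(f"expected a 2-D grayscale image, got shape {arr.shape}")
    if arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValidationError(f"image must be at least 2x2, got shape {arr.shape}")
    if arr.min() < 0 or arr.max() > 255:
        raise ValidationError("pixel values must lie in [0, 255]")
    return arr


def _as_mask(mask) -> np.ndarray:
    arr = np.asarray(mask)
    if arr.ndim != 2:
        raise ValidationError(f"expected a 2-D mask, got shape {arr.shape}")
    if not np.isin(arr, (0, 1)).all():
        raise ValidationError("mask values must be 0 or 1")
    return arr.astype(np.uint8)


def binarize(image, threshold_norm: float = 0.05) -> np.ndarray:
    """Threshold an 8-bit image at ``threshold_norm * 255``.

    A pixel maps to 1 iff its value is strictly greater than the cut, so
    with the default threshold an intensity of 12 maps to 0 and 13 to 1
    (cut at 12.75).
    """
    if not 0.0 < threshold_norm < 1.0:
        raise ValidationError(f"threshold_norm must be in (0, 1), got {threshold_norm}")
    arr = _as_gray(image)
    return (arr > threshold_norm * 255).astype(np.uint8)


def largest_component_mask(mask) -> np.ndarray:
    """Keep only the largest 8-connected foreground component, holes filled.

    Raises :class:`EmptyForegroundError` if the mask has no foreground
    pixel, which signals a background-only image.
    """
    arr = _as_mask(mask)
    if not arr.any():
        raise EmptyForegroundError("no foreground found")
    labels, n = ndimage.label(arr, structure=_STRUCT8)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(arr), labels, index=np.arange(1, n + 1))
        keep = int(np.argmax(sizes)) + 1
        arr = (labels == keep).astype(np.uint8)
    return ndimage.binary_fill_holes(arr).astype(np.uint8)


def extract_foreground(image, mask) -> np.ndarray:
    """Elementwise product of image and binary mask (background zeroed)."""
    img = _as_gray(image)
    msk = _as_mask(mask)
    if img.shape != msk.shape:
        raise DataError(f"shape mismatch: image {img.shape} vs mask {msk.shape}")
    return (img * msk).astype(img.dtype)


def downsample_mean2x2(image) -> np.ndarray:
    """Halve both dimensions by averaging disjoint 2x2 blocks.

    Block means are rounded half-up to keep an integer 8-bit image; an odd
    trailing row/column is dropped.
    """
    arr = _as_gray(image)
    h, w = arr.shape[0] // 2 * 2, arr.shape[1] // 2 * 2
    blocks = arr[:h, :w].astype(np.float64).reshape(h // 2, 2, w // 2, 2)
    means = blocks.mean(axis=(1, 3))
    return np.floor(means + 0.5).astype(np.uint8)


def preprocess_image(image, threshold_norm: float = 0.05, downsample: bool = True) -> np.ndarray:
    """Full chain: binarize, largest component + hole fill, mask, downsample."""
    mask = binarize(image, threshold_norm)
    mask = largest_component_mask(mask)
    fg = extract_foreground(image, mask)
    return downsample_mean2x2(fg) if downsample else fg
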