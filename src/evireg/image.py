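"""Image container conventions and raster I/O.

Images are plain 2-D float64 numpy arrays with intensities in [0, 1].
8-bit inputs are divided by 255, 16-bit by 65535; colour inputs are
converted to luma with the ITU-R BT.601 weights (0.299, 0.587, 0.114)
before any processing.  Supported raster formats: PNG, TIFF, PGM.
"""

from __future__ import annotations

import numpy as np
import imageio.v3 as iio

__all__ = ["as_image", "load_image", "save_image", "MIN_SIZE"]

MIN_SIZE = 8  # minimum side length for similarity computations

_BT601 = np.array([0.299, 0.587, 0.114])


def as_image(arr, *, check_size: bool = False) -> np.ndarray:
    """Validate and coerce an array to the package's image convention."""
    img = np.asarray(arr, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale image, got shape {img.shape}")
    if not np.all(np.isfinite(img)):
        raise ValueError("image contains non-finite values")
    if img.min() < 0.0 or img.max() > 1.0:
        raise ValueError("image intensities must lie in [0, 1]")
    if check_size and min(img.shape) < MIN_SIZE:
        raise ValueError(f"image sides must be >= {MIN_SIZE} pixels")
    return img


def load_image(path) -> np.ndarray:
    """Load a raster file as a [0, 1] grayscale image."""
    raw = iio.imread(path)
    arr = np.asarray(raw)
    if arr.ndim == 3:  # colour (drop any alpha channel first)
        arr = arr[..., :3].astype(np.float64) @ _BT601
    else:
        arr = arr.astype(np.float64)
    if raw.dtype == np.uint8:
        arr = arr / 255.0
    elif raw.dtype == np.uint16:
        arr = arr / 65535.0
    else:
        # float input: assume already [0,1] but clip fp slop
        arr = np.clip(arr, 0.0, 1.0)
    return as_image(np.clip(arr, 0.0, 1.0))


def save_image(path, img) -> None:
    """Save a [0, 1] image as 8-bit."""
    img = as_image(img)
    iio.imwrite(path, np.round(img * 255.0).astype(np.uint8))
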