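"""Raster IO helpers: float images in [0, 1] and 0/255 binary masks."""

from __future__ import annotations

import numpy as np
import imageio.v3 as iio

__all__ = ["read_image", "write_image", "read_mask", "write_mask"]


def read_image(path) -> np.ndarray:
    """Read PNG/TIFF/JPEG/PPM as float in [0, 1] (grayscale or RGB)."""
    arr = iio.imread(path)
    arr = np.asarray(arr)
    if arr.dtype == np.uint8:
        return arr / 255.0
    if arr.dtype == np.uint16:
        return arr / 65535.0
    return arr.astype(float)


def write_image(path, img: np.ndarray, bitdepth: int = 8) -> None:
    img = np.clip(np.asarray(img, float), 0.0, 1.0)
    if bitdepth == 16:
        iio.imwrite(path, (img * 65535 + 0.5).astype(np.uint16))
    else:
        iio.imwrite(path, (img * 255 + 0.5).astype(np.uint8))


def read_mask(path) -> np.ndarray:
    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr[..., 0]
    return arr != 0


def write_mask(path, mask: np.ndarray) -> None:
    iio.imwrite(path, np.where(np.asarray(mask, bool), 255, 0).astype(np.uint8))
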