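"""Small image / mask I/O helpers (PNG, TIFF via imageio)."""

from __future__ import annotations

import numpy as np
import imageio.v3 as iio

__all__ = ["read_image", "write_image", "read_mask", "write_mask"]


def read_image(path) -> np.ndarray:
    """Read an image as uint8 (grayscale stays 2-D, color stays RGB)."""
    img = iio.imread(path)
    if img.dtype != np.uint8:
        img = np.clip(img, 0, 255).astype(np.uint8)
    if img.ndim == 3 and img.shape[2] == 4:  # drop alpha
        img = img[:, :, :3]
    return img


def write_image(path, img: np.ndarray) -> None:
    iio.imwrite(path, np.asarray(img, dtype=np.uint8))


def read_mask(path) -> np.ndarray:
    """Read a binary mask PNG (any nonzero / >127 pixel is foreground)."""
    img = read_image(path)
    if img.ndim == 3:
        img = img[:, :, 0]
    return img > 127


def write_mask(path, mask: np.ndarray) -> None:
    iio.imwrite(path, (np.asarray(mask, dtype=bool) * np.uint8(255)))
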