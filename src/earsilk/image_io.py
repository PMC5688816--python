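"""Thin PNG/TIFF read-write helpers used across the package."""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np


def read_image(path: str | Path) -> np.ndarray:
    img = iio.imread(path)
    if img.ndim == 3 and img.shape[2] == 4:
        img = img[..., :3]
    return img


def write_image(path: str | Path, img: np.ndarray) -> None:
    iio.imwrite(path, np.asarray(img))


def read_mask(path: str | Path) -> np.ndarray:
    """8-bit 0/255 PNG -> boolean raster."""
    img = iio.imread(path)
    if img.ndim == 3:
        img = img[..., 0]
    return img > 127


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    iio.imwrite(path, (np.asarray(mask, dtype=bool) * np.uint8(255)))
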