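"""Image and sidecar-file input/output helpers."""

from __future__ import annotations

import pathlib

import numpy as np
import imageio.v3 as iio

__all__ = ["load_image", "save_image"]


def load_image(path) -> np.ndarray:
    """Read an 8-bit grayscale image (PNG/TIFF); RGB inputs are averaged."""
    img = iio.imread(path)
    if img.ndim == 3:
        img = img[..., :3].mean(axis=2)
    if img.dtype != np.uint8:
        img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return img


def save_image(path, image: np.ndarray) -> None:
    """Write a grayscale or RGB image; boolean masks are scaled to 0/255."""
    path = pathlib.Path(path)
    arr = np.asarray(image)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8) * 255
    elif arr.dtype != np.uint8:
        arr = np.clip(np.rint(arr), 0, 255).astype(np.uint8)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, arr)
    else:
        iio.imwrite(path, arr)
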