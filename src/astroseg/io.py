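"""TIFF and table I/O."""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
import tifffile

from .image import Image2D

__all__ = ["read_image", "write_image", "write_label_tiff"]

_ALLOWED = (np.uint8, np.uint16)


def read_image(path, channels=None, layout: str = "pages", pixel_size: float = 1.0):
    """Read one or more channels from an 8/16-bit unsigned grayscale TIFF.

    ``layout='pages'`` treats multi-page files as one channel per page;
    ``layout='axis'`` treats the leading axis of a 3-D array as channels.
    ``channels`` is a 0-based index or list of indices (None = all).
    Returns a list of Image2D, one per requested channel.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"{path}: no such file")
    try:
        arr = tifffile.imread(path)
    except Exception as exc:  # pragma: no cover - depends on file corruption
        raise ValueError(f"{path}: unreadable TIFF ({exc})") from exc
    if arr.dtype not in (np.dtype(np.uint8), np.dtype(np.uint16)):
        raise ValueError(f"{path}: unsupported dtype {arr.dtype}; need 8- or 16-bit unsigned")
    if layout not in ("pages", "axis"):
        raise ValueError("layout must be 'pages' or 'axis'")
    if arr.ndim == 2:
        stack = arr[None]
    elif arr.ndim == 3:
        stack = arr
    else:
        raise ValueError(f"{path}: expected 2-D or 3-D data, got shape {arr.shape}")
    n = stack.shape[0]
    if channels is None:
        idx = list(range(n))
    elif np.isscalar(channels):
        idx = [int(channels)]
    else:
        idx = [int(c) for c in channels]
    for c in idx:
        if not 0 <= c < n:
            raise ValueError(f"{path}: channel {c} out of range (file has {n})")
    return [Image2D(stack[c], pixel_size=pixel_size) for c in idx]


def write_image(path, img, dtype=np.uint16) -> None:
    """Write an Image2D (or array) as an unsigned TIFF, clipping to range."""
    a = np.asarray(getattr(img, "pixels", img))
    info = np.iinfo(dtype)
    out = np.clip(np.round(a), info.min, info.max).astype(dtype)
    tifffile.imwrite(path, out)


def write_label_tiff(path, labels) -> None:
    """Write an integer label raster (0 = background) as 16-bit TIFF."""
    write_image(path, np.asarray(labels), dtype=np.uint16)


def write_table(path, df: pd.DataFrame) -> None:
    df.to_csv(path, index=False)
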