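"""Minimal raster container shared by every pipeline stage."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Image2D", "as_image"]


@dataclass(frozen=True)
class Image2D:
    """A 2-D grayscale intensity raster.

    Parameters
    ----------
    pixels
        2-D array of finite, non-negative intensities (arbitrary units).
        Any numeric dtype is accepted; operations view it as float.
    pixel_size
        Physical side length of one pixel (µm/px). Purely metadata: all
        geometry is computed in pixels and converted on output.
    """

    pixels: np.ndarray
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        a = np.asarray(self.pixels)
        if a.ndim != 2 or a.shape[0] < 1 or a.shape[1] < 1:
            raise ValueError("Image2D requires a 2-D array with height, width >= 1")
        if not np.all(np.isfinite(a)):
            raise ValueError("image intensities must be finite")
        if a.size and float(a.min()) < 0:
            raise ValueError("image intensities must be non-negative")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        object.__setattr__(self, "pixels", a)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def as_image(obj, pixel_size: float | None = None) -> Image2D:
    """Coerce an ndarray (or Image2D) to an Image2D."""
    if isinstance(obj, Image2D):
        if pixel_size is not None and pixel_size != obj.pixel_size:
            return Image2D(obj.pixels, pixel_size)
        return obj
    return Image2D(np.asarray(obj), pixel_size if pixel_size is not None else 1.0)
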