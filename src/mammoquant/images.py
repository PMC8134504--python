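"""Raster image container with physical pixel size.

Coordinates are 0-based ``(row, col)`` with the origin at the top-left
corner, matching numpy indexing. Physical scale is carried as microns per
pixel; when an image comes from a flatbed scan the scale is derived from
the scan resolution as ``25400 / dpi`` (25.4 mm per inch).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import tifffile

from .errors import ParameterError

UM_PER_INCH = 25400.0


@dataclass
class RasterImage:
    """A 2-D pixel grid (scalar or RGB) with its physical pixel size in µm."""

    pixels: np.ndarray
    pixel_size_um: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim not in (2, 3):
            raise ParameterError("pixels must be a 2-D grid or an RGB stack")
        if self.pixels.ndim == 3 and self.pixels.shape[2] != 3:
            raise ParameterError("colour images must have exactly 3 channels")
        if not self.pixel_size_um > 0:
            raise ParameterError("pixel_size_um must be > 0")

    @property
    def is_rgb(self) -> bool:
        return self.pixels.ndim == 3

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]

    @classmethod
    def from_dpi(cls, pixels: np.ndarray, dpi: float) -> "RasterImage":
        """Build an image from a scan, converting resolution to µm/px."""
        if not dpi > 0:
            raise ParameterError("dpi must be > 0")
        return cls(pixels=pixels, pixel_size_um=pixel_size_from_dpi(dpi))

    @classmethod
    def read(cls, path, pixel_size_um: float | None = None,
             dpi: float | None = None) -> "RasterImage":
        if (pixel_size_um is None) == (dpi is None):
            raise ParameterError("give exactly one of pixel_size_um or dpi")
        if str(path).lower().endswith((".tif", ".tiff")):
            pixels = tifffile.imread(str(path))
        else:
            import imageio.v3 as iio
            pixels = np.asarray(iio.imread(str(path)))
        if dpi is not None:
            return cls.from_dpi(pixels, dpi)
        return cls(pixels=pixels, pixel_size_um=float(pixel_size_um))

    def write(self, path) -> None:
        tifffile.imwrite(str(path), self.pixels)


def pixel_size_from_dpi(dpi: float) -> float:
    """Physical pixel size in µm of a scan at the given dots-per-inch."""
    if not dpi > 0:
        raise ParameterError("dpi must be > 0")
    return UM_PER_INCH / float(dpi)
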