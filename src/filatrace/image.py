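"""Calibrated raster images and file I/O.

The working object of the whole pipeline is :class:`RasterImage`: a 2-D
non-negative intensity field with a physical pixel size in micrometres.
Pixel centres sit at integer (row, col) coordinates, origin top-left,
row-major. Orientation angles elsewhere in the package are measured from
the horizontal (column) axis, counter-clockwise in the conventional
mathematical sense, i.e. with the row axis pointing *up*.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import imageio.v3 as iio
import tifffile


class FilatraceError(Exception):
    """Base class for errors raised by this package."""


class ParameterError(FilatraceError, ValueError):
    """A numeric or structural parameter is outside its documented range."""


@dataclass
class RasterImage:
    """A calibrated 2-D grayscale intensity field.

    Parameters
    ----------
    pixels
        2-D array of finite, non-negative intensities (any float or
        integer dtype; converted to float64).
    pixel_size_um
        Physical edge length of one pixel in micrometres; must be > 0.
    meta
        Free-form metadata (e.g. the intensity scale factor used when the
        image was written to 16-bit TIFF).
    """

    pixels: np.ndarray
    pixel_size_um: float = 1.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ParameterError(
                f"pixels must be a non-empty 2-D array, got shape {self.pixels.shape}"
            )
        if not np.all(np.isfinite(self.pixels)):
            raise ParameterError("pixels must be finite")
        if self.pixel_size_um <= 0:
            raise ParameterError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def normalized(self) -> "RasterImage":
        """Min-max normalize intensities to [0, 1].

        A constant image maps to all zeros. Downstream thresholds
        (Laplacian quantile, concavity) are defined on this scale.
        """
        lo = float(self.pixels.min())
        hi = float(self.pixels.max())
        if hi > lo:
            px = (self.pixels - lo) / (hi - lo)
        else:
            px = np.zeros_like(self.pixels)
        return RasterImage(px, self.pixel_size_um, dict(self.meta))

    def copy_with(self, pixels: np.ndarray) -> "RasterImage":
        return RasterImage(pixels, self.pixel_size_um, dict(self.meta))


def read_image(path: str | Path, pixel_size_um: float = 1.0,
               channel: int | None = None) -> RasterImage:
    """Read a grayscale TIFF/PNG micrograph.

    Multi-channel inputs require an explicit ``channel`` index (for
    phalloidin-TRITC actin stains this is typically the red channel, 0).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image not found: {path}")
    arr = iio.imread(path)
    if arr.ndim == 3:
        if channel is None:
            raise ParameterError(
                f"{path} has {arr.shape[-1]} channels; pass an explicit channel index"
            )
        arr = arr[..., channel]
    return RasterImage(np.asarray(arr, dtype=np.float64), pixel_size_um)


def write_image_16bit(image: RasterImage, path: str | Path) -> float:
    """Write intensities as 16-bit grayscale TIFF by linear scaling.

    The scale factor mapping stored integer values back to the original
    float intensities is returned and recorded in the TIFF description so
    tests can invert the quantization.
    """
    path = Path(path)
    hi = float(image.pixels.max())
    scale = hi / 65535.0 if hi > 0 else 1.0
    data = np.round(image.pixels / scale).astype(np.uint16)
    tifffile.imwrite(
        path, data,
        description=f"filatrace scale={scale!r} pixel_size_um={image.pixel_size_um!r}",
    )
    return scale
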