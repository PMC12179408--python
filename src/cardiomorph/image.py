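"""Calibrated rasters and TIFF input/output.

Every downstream measurement is expressed in physical units, so images carry
their pixel (or voxel) size with them.  2D micrographs are stored as float
rasters with a pixel size in micrometres; z-stacks additionally carry a
(z, y, x) voxel size triple.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import tifffile


@dataclass
class CalibratedImage:
    """A 2D intensity raster with physical pixel calibration.

    Parameters
    ----------
    pixels : ndarray, shape (rows, cols)
        Intensity raster (any real dtype; synthetic images are float32).
    pixel_size_um : float
        Edge length of one pixel in micrometres. Must be positive.
    channel_name : str
        Free-text channel description (e.g. ``"actin"``).
    """

    pixels: np.ndarray
    pixel_size_um: float
    channel_name: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("pixels must be a non-empty 2D raster")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def pixel_area_um2(self) -> float:
        return self.pixel_size_um ** 2


def write_tiff(path, image: CalibratedImage) -> None:
    """Write a 2D calibrated image as TIFF with the pixel size in the
    resolution tags (pixels per micrometre, unit-less RESUNIT as ImageJ does
    for micron-calibrated images)."""
    res = 1.0 / image.pixel_size_um
    tifffile.imwrite(
        path,
        np.asarray(image.pixels),
        resolution=(res, res),
        metadata={"unit": "um", "channel": image.channel_name},
    )


def read_tiff(path, pixel_size_um: float | None = None,
              channel_name: str = "") -> CalibratedImage:
    """Read a 2D TIFF; pixel size is taken from the resolution tags unless
    given explicitly."""
    with tifffile.TiffFile(path) as tf:
        page = tf.pages[0]
        data = page.asarray()
        if pixel_size_um is None:
            try:
                xres = page.tags["XResolution"].value
                num, den = xres
                if num > 0:
                    pixel_size_um = den / num
            except (KeyError, TypeError, ZeroDivisionError):
                pixel_size_um = None
    if pixel_size_um is None:
        raise ValueError(
            "pixel size not present in TIFF metadata; pass pixel_size_um")
    if data.ndim == 3:  # multi-channel page; keep first plane
        data = data[0]
    return CalibratedImage(data, pixel_size_um, channel_name)


def write_stack(path, stack: np.ndarray, voxel_um: tuple[float, float, float]) -> None:
    """Write a (z, y, x) stack as a multi-page TIFF with voxel size metadata."""
    vz, vy, vx = voxel_um
    tifffile.imwrite(
        path,
        np.asarray(stack),
        resolution=(1.0 / vx, 1.0 / vy),
        metadata={"unit": "um", "spacing": vz, "axes": "ZYX"},
    )


def read_stack(path) -> np.ndarray:
    """Read a multi-page TIFF z-stack as a (z, y, x) array."""
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    return data
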