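"""RGB <-> optical-density conversion and image I/O for bright-field IHC.

Bright-field absorption follows the Beer-Lambert law: transmitted intensity
``I = Io * exp(-OD)`` per channel, so the optical density ``OD = -ln(I/Io)``
of a pixel is (approximately) linear in chromogen concentration.  All stain
separation happens in OD space; this module owns the transform in both
directions plus the near-white background mask.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np

#: Maximum intensity of an 8-bit image (the reference white level Io).
DEFAULT_IO_LEVEL = 255

#: Intensity clip floor applied before the log so zero pixels stay finite.
DEFAULT_EPS_FLOOR = 1.0

#: Default OD 1-norm below which a pixel counts as (near-white) background.
DEFAULT_TAU_BG = 0.05


class ImagingError(ValueError):
    """Raised for invalid image inputs (empty, wrong depth, negatives)."""


@dataclass
class RGBImage:
    """An RGB bright-field image flattened to channels-by-pixels.

    Attributes
    ----------
    pixels : (3, N) ndarray
        Integer intensities, rows = R, G, B; pixels in row-major order.
    width, height : int
        Original raster dimensions, ``width * height == N``.
    io_level : int
        Maximum representable intensity (255 for 8-bit acquisition).
    """

    pixels: np.ndarray
    width: int
    height: int
    io_level: int = DEFAULT_IO_LEVEL

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.shape[0] != 3:
            raise ImagingError(f"pixels must be 3xN, got {self.pixels.shape}")
        if self.pixels.shape[1] == 0 or self.width * self.height != self.pixels.shape[1]:
            raise ImagingError(
                f"width*height = {self.width * self.height} does not match "
                f"N = {self.pixels.shape[1]} (must be positive and equal)"
            )
        if self.pixels.min() < 0 or self.pixels.max() > self.io_level:
            raise ImagingError(f"intensities must lie in [0, {self.io_level}]")

    @property
    def n_pixels(self) -> int:
        return self.pixels.shape[1]

    @classmethod
    def from_array(cls, arr: np.ndarray, io_level: int = DEFAULT_IO_LEVEL) -> "RGBImage":
        """Build from an (H, W, 3) raster array (alpha dropped with a warning)."""
        arr = np.asarray(arr)
        if arr.ndim != 3 or arr.shape[2] not in (3, 4):
            raise ImagingError(f"expected an (H, W, 3) color image, got shape {arr.shape}")
        if arr.shape[2] == 4:
            warnings.warn("alpha channel dropped", stacklevel=2)
            arr = arr[:, :, :3]
        h, w = arr.shape[:2]
        return cls(arr.reshape(h * w, 3).T, width=w, height=h, io_level=io_level)

    def to_array(self) -> np.ndarray:
        """Return the (H, W, 3) uint8 raster."""
        return (
            self.pixels.T.reshape(self.height, self.width, 3)
            .astype(np.uint8, copy=False)
        )


@dataclass
class ODMatrix:
    """Relative optical densities of one image: a non-negative 3xN matrix."""

    values: np.ndarray
    width: int
    height: int
    io_level: int = DEFAULT_IO_LEVEL

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != 3:
            raise ImagingError(f"OD values must be 3xN, got {self.values.shape}")
        if not np.isfinite(self.values).all() or self.values.min() < 0:
            raise ImagingError("OD entries must be finite and non-negative")

    @property
    def n_pixels(self) -> int:
        return self.values.shape[1]


def rgb_to_od(image: RGBImage, eps_floor: float = DEFAULT_EPS_FLOOR) -> ODMatrix:
    """Beer-Lambert transform of an image to relative optical density.

    Entry (i, n) is ``-ln(clip(I_in, eps_floor, Io) / Io)``.  The clip floor
    (default one intensity level) keeps fully black pixels finite.
    """
    if image.n_pixels == 0:
        raise ImagingError("empty image")
    intens = np.clip(image.pixels.astype(float), eps_floor, image.io_level)
    od = -np.log(intens / image.io_level)
    return ODMatrix(od, width=image.width, height=image.height, io_level=image.io_level)


def od_to_rgb(
    w: np.ndarray,
    h: np.ndarray,
    io_level: int = DEFAULT_IO_LEVEL,
    width: int | None = None,
    height: int | None = None,
) -> RGBImage:
    """Render a single stain back to RGB: ``I = round(Io * exp(-w h))``.

    Parameters
    ----------
    w : (3,) array
        Non-negative OD color vector of the stain.
    h : (N,) array
        Non-negative concentration of the stain at each pixel.

    Zero concentration renders a white pixel; large products saturate black.
    """
    w = np.asarray(w, dtype=float).reshape(3)
    h = np.asarray(h, dtype=float).reshape(-1)
    if w.min() < 0 or h.min() < 0:
        raise ImagingError("stain vector and concentrations must be non-negative")
    od = np.outer(w, h)
    intens = np.clip(np.rint(io_level * np.exp(-od)), 0, io_level)
    n = h.size
    if width is None or height is None:
        width, height = n, 1
    return RGBImage(intens.astype(np.uint8), width=width, height=height, io_level=io_level)


def background_mask(od: ODMatrix, tau_bg: float = DEFAULT_TAU_BG) -> np.ndarray:
    """Boolean N-vector, True where the OD column 1-norm is below ``tau_bg``.

    Near-white pixels carry almost no stain; their planar angle is noise
    dominated, so callers exclude them from the angular density profile
    (they still take part in deconvolution, where their concentrations
    come out ~0 anyway).
    """
    if tau_bg < 0:
        raise ImagingError("tau_bg must be >= 0")
    return np.abs(od.values).sum(axis=0) < tau_bg


def read_image(path: str | Path, io_level: int = DEFAULT_IO_LEVEL) -> RGBImage:
    """Read an 8-bit RGB TIFF/PNG from disk."""
    arr = iio.imread(Path(path))
    if arr.ndim == 2:
        raise ImagingError(f"{path}: grayscale image, two-stain RGB required")
    if arr.dtype != np.uint8:
        raise ImagingError(f"{path}: only 8-bit images are supported (got {arr.dtype})")
    return RGBImage.from_array(arr, io_level=io_level)


def write_image(path: str | Path, image: RGBImage) -> None:
    """Write an image as PNG or TIFF (decided by the file extension)."""
    iio.imwrite(Path(path), image.to_array())
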