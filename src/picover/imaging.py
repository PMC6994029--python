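"""Image containers, ROI cropping, colour-space conversion and contrast stretch.

Pigment-cover analysis works on 24-bit RGB photographs of animal tissue on a
uniform background.  Everything downstream (colour thresholding, particle
analysis) operates on 8-bit channel planes, so this module keeps all images as
H×W×3 byte rasters tagged with their colour space:

* ``SRGB``  — the camera's non-linear display space.
* ``HSB``   — hue/saturation/brightness, each scaled to [0, 255]; hue covers
  the full colour circle (0 = red, 85 ≈ green, 170 ≈ blue).  This is the
  space in which colour-band thresholds are expressed.
* ``LAB8``  — CIELAB (D65, 2° observer) byte-packed: L* mapped from [0, 100]
  to [0, 255]; a*/b* offset by +128 so that 128 ≈ 0.  Conversion performs the
  sRGB gamma linearization internally, so thresholding the L channel of a
  LAB8 image operates on (perceptually scaled) linear-light data.

Conversions are computed in floating point via :mod:`skimage.color` and
rounded half-away-from-zero to bytes at the end.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from enum import Enum
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile
from skimage import color as _skcolor


class ColorSpace(Enum):
    SRGB = "srgb"
    HSB = "hsb"
    LAB8 = "lab8"


def _round_half_away(x: np.ndarray) -> np.ndarray:
    """Round to nearest integer, halves away from zero (values here are ≥ 0)."""
    return np.floor(np.asarray(x, dtype=np.float64) + 0.5)


@dataclass(frozen=True)
class RasterImage:
    """An H×W×3 byte raster with a colour-space tag.

    Parameters
    ----------
    pixels : numpy.ndarray
        ``uint8`` array of shape (H, W, 3).
    space : ColorSpace
        Colour space of the three channels.
    pixel_size : float, optional
        Physical size of one pixel in µm; used to resolve physical ROI sizes
        (e.g. a 1 mm² crop).
    """

    pixels: np.ndarray
    space: ColorSpace = ColorSpace.SRGB
    pixel_size: float | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"pixels must be H×W×3, got shape {px.shape}")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("image must contain at least one pixel")
        if px.dtype != np.uint8:
            raise ValueError(f"pixels must be uint8, got {px.dtype}")
        if self.pixel_size is not None and not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    def channel(self, index: int) -> np.ndarray:
        """Return one channel as an H×W byte plane (a view)."""
        return self.pixels[:, :, index]


@dataclass(frozen=True)
class ROI:
    """Rectangular region of interest: 0-based, row-major, half-open."""

    row0: int
    col0: int
    height: int
    width: int

    def __post_init__(self) -> None:
        if self.row0 < 0 or self.col0 < 0:
            raise ValueError("ROI origin must be non-negative")
        if self.height < 1 or self.width < 1:
            raise ValueError("ROI must contain at least one pixel")

    @property
    def area(self) -> int:
        return self.height * self.width

    def check_within(self, img: RasterImage) -> None:
        if self.row0 + self.height > img.height:
            raise ValueError(
                f"ROI bottom edge {self.row0 + self.height} exceeds image "
                f"height {img.height}"
            )
        if self.col0 + self.width > img.width:
            raise ValueError(
                f"ROI right edge {self.col0 + self.width} exceeds image "
                f"width {img.width}"
            )


def crop_roi(img: RasterImage, roi: ROI) -> RasterImage:
    """Crop ``img`` to ``roi``; colour space and pixel size are preserved."""
    roi.check_within(img)
    sub = img.pixels[
        roi.row0 : roi.row0 + roi.height, roi.col0 : roi.col0 + roi.width
    ].copy()
    return replace(img, pixels=sub)


def centered_square_roi(img: RasterImage, area_mm2: float) -> ROI:
    """Centered square ROI of the given physical area (e.g. 1 mm²).

    The side length is ``sqrt(area_mm2) * 1000 / pixel_size`` pixels, rounded
    to the nearest whole pixel.  Requires ``img.pixel_size`` (µm/pixel).
    """
    if img.pixel_size is None:
        raise ValueError("image has no pixel_size; cannot resolve a physical ROI")
    if area_mm2 <= 0:
        raise ValueError("area_mm2 must be positive")
    side = int(round(math.sqrt(area_mm2) * 1000.0 / img.pixel_size))
    side = max(side, 1)
    if side > img.height or side > img.width:
        raise ValueError(
            f"{area_mm2} mm² needs a {side}px square, larger than the image"
        )
    return ROI((img.height - side) // 2, (img.width - side) // 2, side, side)


def _require_space(img: RasterImage, space: ColorSpace, op: str) -> None:
    if img.space is not space:
        raise ValueError(f"{op} requires a {space.name} image, got {img.space.name}")


def srgb_to_hsb(img: RasterImage) -> RasterImage:
    """Convert sRGB bytes to HSB bytes (hexcone model).

    B = max(R,G,B); S = (max−min)/max (0 for black); H = sector angle on the
    colour circle.  All three are scaled to [0, 255]; achromatic pixels get
    hue 0 by convention.
    """
    _require_space(img, ColorSpace.SRGB, "srgb_to_hsb")
    hsv = _skcolor.rgb2hsv(img.pixels)
    out = _round_half_away(hsv * 255.0).astype(np.uint8)
    return replace(img, pixels=out, space=ColorSpace.HSB)


def hsb_to_srgb(img: RasterImage) -> RasterImage:
    """Inverse hexcone map, HSB bytes back to sRGB bytes (±1 round trip)."""
    _require_space(img, ColorSpace.HSB, "hsb_to_srgb")
    rgb = _skcolor.hsv2rgb(img.pixels.astype(np.float64) / 255.0)
    out = _round_half_away(rgb * 255.0).astype(np.uint8)
    return replace(img, pixels=out, space=ColorSpace.SRGB)


def srgb_to_lab(img: RasterImage) -> RasterImage:
    """Convert sRGB to byte-packed CIELAB (gamma decode → XYZ → L*a*b*).

    Uses the IEC 61966-2-1 piecewise gamma decode and the D65 white point /
    2° observer.  L* ∈ [0, 100] is scaled to [0, 255]; a*/b* are offset by
    +128 (clipped to the byte range).
    """
    _require_space(img, ColorSpace.SRGB, "srgb_to_lab")
    lab = _skcolor.rgb2lab(img.pixels.astype(np.float64) / 255.0)
    out = np.empty_like(img.pixels)
    out[:, :, 0] = _round_half_away(lab[:, :, 0] * 255.0 / 100.0).astype(np.uint8)
    for c in (1, 2):
        out[:, :, c] = np.clip(_round_half_away(lab[:, :, c]) + 128, 0, 255).astype(
            np.uint8
        )
    return replace(img, pixels=out, space=ColorSpace.LAB8)


def enhance_contrast(channel: np.ndarray, saturated_fraction: float) -> np.ndarray:
    """Percentile contrast stretch of a byte plane.

    Finds clip values ``low``/``high`` from the histogram such that at most
    ``saturated_fraction/2`` of the pixels lie strictly below ``low`` and at
    most the same fraction strictly above ``high``, then linearly rescales
    [low, high] → [0, 255] with clamping.  ``saturated_fraction=0`` is a
    plain min–max stretch.  A constant channel is returned unchanged with a
    warning, since no stretch is possible.
    """
    plane = np.asarray(channel)
    if plane.dtype != np.uint8:
        raise ValueError("channel must be a uint8 plane")
    if not 0 <= saturated_fraction < 1:
        raise ValueError("saturated_fraction must be in [0, 1)")
    counts = np.bincount(plane.ravel(), minlength=256)
    n = int(counts.sum())
    allowed = int(math.floor(n * saturated_fraction / 2.0))
    below = np.concatenate(([0], np.cumsum(counts)[:-1]))  # pixels strictly < v
    above = n - np.cumsum(counts)  # pixels strictly > v
    occupied = np.nonzero(counts)[0]
    low = int(max(v for v in occupied if below[v] <= allowed))
    high = int(min(v for v in occupied if above[v] <= allowed))
    if low >= high:
        warnings.warn(
            "channel has no dynamic range to stretch; returned unchanged",
            stacklevel=2,
        )
        return plane.copy()
    scaled = (plane.astype(np.float64) - low) * (255.0 / (high - low))
    return np.clip(_round_half_away(scaled), 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# File IO: uncompressed TIFF and PNG in, PNG out for masks/overlays.

def read_image(path: str | Path, pixel_size: float | None = None) -> RasterImage:
    """Read a TIFF or PNG file as an sRGB :class:`RasterImage`.

    Images with an alpha channel are rejected: transparency in the file would
    silently corrupt cover fractions.
    """
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    arr = np.asarray(arr)
    if arr.ndim == 3 and arr.shape[2] == 4:
        raise ValueError(f"{path.name}: alpha channel not supported; flatten first")
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"{path.name}: expected an RGB image, got shape {arr.shape}")
    if arr.dtype != np.uint8:
        raise ValueError(f"{path.name}: expected 8-bit channels, got {arr.dtype}")
    return RasterImage(arr, ColorSpace.SRGB, pixel_size)


def write_png(path: str | Path, img: RasterImage) -> None:
    iio.imwrite(Path(path), img.pixels, extension=".png")


def write_mask_png(path: str | Path, mask: np.ndarray) -> None:
    """Write a binary mask as an 8-bit PNG (foreground = 255)."""
    iio.imwrite(
        Path(path), (np.asarray(mask, bool) * np.uint8(255)), extension=".png"
    )
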