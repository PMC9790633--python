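"""Reading, writing and mask-based contrast enhancement of fundus images.

Fluorescein angiograms render perfused vessels bright against the fundus
background.  In hypopigmented eyes the background itself is bright, so the
vessel/background contrast can be too low for threshold detection; the
remedy implemented here is the classic pre-processing step of painting the
(manually or externally selected) vessel pixels to the maximum representable
intensity before scanning.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .errors import FormatError, InputError

log = logging.getLogger(__name__)

#: Minimum image side length.  Anything smaller cannot hold even the smallest
#: sensible measurement annulus (disc radius ~8 px, outer ring at 4x).
MIN_SIDE = 64

_LUMA_WEIGHTS = np.array([0.2126, 0.7152, 0.0722])  # ITU-R BT.709


@dataclass(frozen=True)
class FundusImage:
    """A single-channel fundus image with its intensity scale.

    Parameters
    ----------
    pixels
        2-D float array, (row, col), origin top-left.
    bit_depth
        8 or 16; fixes ``max_value``.
    source_path
        Where the image came from, if it was read from disk.
    """

    pixels: np.ndarray
    bit_depth: int = 8
    source_path: str | None = None
    max_value: int = field(init=False)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2:
            raise InputError(f"expected a 2-D intensity grid, got ndim={px.ndim}")
        if px.shape[0] < MIN_SIDE or px.shape[1] < MIN_SIDE:
            raise InputError(
                f"image {px.shape} is smaller than the {MIN_SIDE}x{MIN_SIDE} "
                "minimum required for a measurement annulus"
            )
        if self.bit_depth not in (8, 16):
            raise FormatError(f"unsupported bit depth {self.bit_depth}")
        object.__setattr__(self, "max_value", (1 << self.bit_depth) - 1)
        if px.min() < 0 or px.max() > self.max_value:
            raise InputError(
                f"pixel values outside [0, {self.max_value}] for "
                f"{self.bit_depth}-bit image"
            )
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


@dataclass(frozen=True)
class VesselMask:
    """Boolean vessel-selection mask, same shape as its image."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise InputError(f"mask must be 2-D, got ndim={px.ndim}")
        object.__setattr__(self, "pixels", px.astype(bool))

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


def _to_intensity(arr: np.ndarray, channel: str) -> np.ndarray:
    """Collapse an (H, W[, C]) array to a single (H, W) channel."""
    if arr.ndim == 2:
        return arr.astype(np.float64)
    if arr.ndim == 3 and arr.shape[2] in (3, 4):
        rgb = arr[..., :3].astype(np.float64)
        if channel == "green":
            return rgb[..., 1]
        if channel == "luminance":
            return rgb @ _LUMA_WEIGHTS
        raise ValueError(f"unknown channel policy {channel!r}")
    raise FormatError(f"unsupported sample layout with shape {arr.shape}")


def load_image(path: str | Path, channel: str = "green") -> FundusImage:
    """Read a PNG/TIFF/JPEG fundus image as a single intensity channel.

    RGB inputs are reduced to the green channel by default, since fluorescein
    emission is imaged in green; ``channel="luminance"`` selects ITU BT.709
    luminance instead.  JPEG inputs are accepted with a warning because lossy
    block artifacts can shift threshold crossings by a pixel or more.
    """
    path = Path(path)
    if not path.is_file():
        raise InputError(f"image file not found: {path}")
    if path.suffix.lower() in (".jpg", ".jpeg"):
        log.warning("JPEG input %s: lossy artifacts may shift crossings", path)
        warnings.warn(
            f"JPEG input {path.name}: lossy artifacts may shift vessel edges",
            stacklevel=2,
        )
    try:
        arr = iio.imread(path)
    except Exception as exc:  # imageio raises various backend errors
        raise InputError(f"cannot read image {path}: {exc}") from exc
    if arr.dtype == np.uint8:
        depth = 8
    elif arr.dtype == np.uint16:
        depth = 16
    elif np.issubdtype(arr.dtype, np.bool_):
        arr, depth = arr.astype(np.uint8) * 255, 8
    else:
        raise FormatError(f"unsupported pixel dtype {arr.dtype} in {path}")
    return FundusImage(_to_intensity(arr, channel), bit_depth=depth,
                       source_path=str(path))


def save_image(image: FundusImage, path: str | Path) -> None:
    """Write a FundusImage losslessly (PNG/TIFF; 8- or 16-bit by depth)."""
    dtype = np.uint8 if image.bit_depth == 8 else np.uint16
    iio.imwrite(Path(path), np.round(image.pixels).astype(dtype))


def load_mask(path: str | Path, shape: tuple[int, int] | None = None) -> VesselMask:
    """Read a binary vessel mask (nonzero = vessel) from a PNG/TIFF file."""
    path = Path(path)
    if not path.is_file():
        raise InputError(f"mask file not found: {path}")
    try:
        arr = iio.imread(path)
    except Exception as exc:
        raise InputError(f"cannot read mask {path}: {exc}") from exc
    if arr.ndim == 3:
        arr = arr[..., :3].max(axis=2)
    mask = VesselMask(arr != 0)
    if shape is not None and mask.shape != tuple(shape):
        raise InputError(
            f"mask shape {mask.shape} does not match image shape {tuple(shape)}"
        )
    return mask


def save_mask(mask: VesselMask, path: str | Path) -> None:
    iio.imwrite(Path(path), mask.pixels.astype(np.uint8) * 255)


def enhance_with_mask(image: FundusImage, mask: VesselMask) -> FundusImage:
    """Paint every masked pixel to the maximum representable intensity.

    This reproduces the contrast-enhancement pre-processing step: selected
    vessel pixels are replaced by a maximum-intensity background (255 for
    8-bit), guaranteeing they exceed any threshold expressed as a fraction of
    ``max_value``.  Unmasked pixels are untouched; the operation is idempotent
    and never decreases a pixel.
    """
    if mask.shape != image.shape:
        raise InputError(
            f"mask shape {mask.shape} does not match image shape {image.shape}"
        )
    px = image.pixels.copy()
    px[mask.pixels] = image.max_value
    return FundusImage(px, bit_depth=image.bit_depth,
                       source_path=image.source_path)
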