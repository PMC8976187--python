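"""Image containers, file I/O and color-space conversion.

Conventions
-----------
* Images are ``H x W x C`` arrays with ``C`` in {1, 3}; values live in
  ``[0, 255]`` regardless of dtype.  Files are converted to RGB at read time;
  BGR exists only as an explicit conversion target.
* **Hue convention**: the H plane is stored in *half-degree units*, i.e. the
  range ``[0, 180)``, so all three HSV planes fit a single ``[0, 255]`` depth.
  Pure red maps to H=0, pure green to H=60, pure blue to H=120.
* HSV planes are kept as floats (S, V in ``[0, 255]``); quantization to
  integers happens only where a histogram or an 8-bit file demands it, so the
  RGB -> HSV -> RGB round trip stays within one intensity level per channel.
* Binary masks hold {0, 1} with foreground = WBC; they serialize as 8-bit PNG
  with foreground 255.  Any nonzero value on read maps to 1, which tolerates
  antialiased ground truth.  Lossy formats are refused for mask writing.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import imageio.v3 as iio
import numpy as np
from skimage import color as _skcolor
from skimage.util import img_as_ubyte

from .errors import FormatError, SemanticError

__all__ = [
    "RasterImage",
    "ChannelImage",
    "BinaryMask",
    "read_image",
    "write_image",
    "read_mask",
    "write_mask",
    "rgb_to_hsv",
    "hsv_to_rgb",
    "extract_channel",
]

#: channel name -> plane index, per channel order
_CHANNEL_INDEX = {
    "RGB": {"R": 0, "G": 1, "B": 2},
    "BGR": {"B": 0, "G": 1, "R": 2},
    "HSV": {"H": 0, "S": 1, "V": 2},
    "GRAY": {"GRAY": 0},
}

_LOSSY_EXTENSIONS = {".jpg", ".jpeg"}


@dataclass
class RasterImage:
    """An ``H x W x C`` intensity grid with declared channel semantics.

    Values must lie in ``[0, 255]``; the H plane of an HSV image additionally
    lies in ``[0, 180)`` (half-degree hue units).
    """

    pixels: np.ndarray
    channel_order: str = "RGB"

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels)
        if arr.ndim == 2:
            arr = arr[:, :, np.newaxis]
        if arr.ndim != 3 or arr.shape[2] not in (1, 3):
            raise FormatError(
                f"image must be HxW or HxWxC with C in {{1,3}}, got shape {arr.shape}"
            )
        if arr.shape[0] < 1 or arr.shape[1] < 1:
            raise FormatError(f"image must have H >= 1 and W >= 1, got {arr.shape}")
        if self.channel_order not in _CHANNEL_INDEX:
            raise FormatError(f"unknown channel order {self.channel_order!r}")
        gray = self.channel_order == "GRAY"
        if gray != (arr.shape[2] == 1):
            raise SemanticError(
                f"channel order {self.channel_order!r} inconsistent with "
                f"{arr.shape[2]} channel(s)"
            )
        if not np.all(np.isfinite(arr.astype(np.float64))):
            raise FormatError("image contains non-finite values")
        lo, hi = float(arr.min()), float(arr.max())
        if lo < 0 or hi > 255:
            raise FormatError(f"pixel values outside [0, 255]: min={lo}, max={hi}")
        if self.channel_order == "HSV" and float(arr[..., 0].max()) >= 180:
            raise FormatError("H plane must lie in [0, 180) (half-degree units)")
        self.pixels = arr

    @property
    def shape(self) -> tuple[int, int]:
        """(H, W) of the image."""
        return self.pixels.shape[:2]

    @property
    def channels(self) -> int:
        return self.pixels.shape[2]


@dataclass
class ChannelImage:
    """A single ``H x W`` plane extracted from a :class:`RasterImage`."""

    pixels: np.ndarray
    source_channel: str = "GRAY"

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels)
        if arr.ndim != 2:
            raise FormatError(f"channel must be 2-D, got shape {arr.shape}")
        if self.source_channel not in {"H", "S", "V", "R", "G", "B", "GRAY"}:
            raise FormatError(f"unknown source channel {self.source_channel!r}")
        if not np.all(np.isfinite(arr.astype(np.float64))):
            raise FormatError("channel contains non-finite values")
        if float(arr.min()) < 0 or float(arr.max()) > 255:
            raise FormatError("channel values outside [0, 255]")
        self.pixels = arr

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class BinaryMask:
    """An ``H x W`` grid of {0, 1}; foreground (1) marks WBC pixels."""

    pixels: np.ndarray
    foreground_semantics: str = field(default="WBC", init=False)

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels)
        if arr.ndim != 2:
            raise FormatError(f"mask must be 2-D, got shape {arr.shape}")
        if arr.dtype == bool:
            arr = arr.astype(np.uint8)
        else:
            uniq = np.unique(arr)
            if not np.all(np.isin(uniq, (0, 1))):
                raise FormatError(f"mask must contain only 0/1, found values {uniq[:8]}")
            arr = arr.astype(np.uint8)
        self.pixels = arr

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def bool(self) -> np.ndarray:
        return self.pixels.astype(np.bool_)

    @property
    def foreground_count(self) -> int:
        return int(self.pixels.sum())

    def __eq__(self, other: object) -> bool:  # masks compare by content
        if not isinstance(other, BinaryMask):
            return NotImplemented
        return self.shape == other.shape and bool(np.array_equal(self.pixels, other.pixels))


def read_image(path: str | os.PathLike) -> RasterImage:
    """Read a JPG/PNG/TIFF file into an RGB (or GRAY) :class:`RasterImage`.

    Grayscale files are promoted to a single GRAY plane; an alpha channel, if
    present, is dropped.  Unreadable or truncated files raise :class:`OSError`
    naming the path.
    """
    try:
        arr = iio.imread(os.fspath(path))
    except OSError:
        raise
    except Exception as exc:  # imageio wraps decoder errors inconsistently
        raise OSError(f"cannot read image file {os.fspath(path)!r}: {exc}") from exc
    if arr.dtype != np.uint8:
        arr = img_as_ubyte(arr)
    if arr.ndim == 2:
        return RasterImage(arr[:, :, np.newaxis], "GRAY")
    if arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
    if arr.ndim == 3 and arr.shape[2] == 3:
        return RasterImage(arr, "RGB")
    raise FormatError(
        f"unsupported channel layout {arr.shape} in {os.fspath(path)!r}"
    )


def write_image(image: RasterImage, path: str | os.PathLike) -> str:
    """Write an RGB or GRAY image to disk (8-bit). Returns the path."""
    if image.channel_order == "HSV":
        raise SemanticError("convert HSV images to RGB before writing")
    arr = np.clip(np.rint(image.pixels), 0, 255).astype(np.uint8)
    if arr.shape[2] == 1:
        arr = arr[:, :, 0]
    elif image.channel_order == "BGR":
        arr = arr[:, :, ::-1]
    path = os.fspath(path)
    try:
        iio.imwrite(path, arr)
    except OSError:
        raise
    except Exception as exc:
        raise OSError(f"cannot write image file {path!r}: {exc}") from exc
    return path


def write_mask(mask: BinaryMask, path: str | os.PathLike) -> str:
    """Serialize a mask as lossless single-channel 8-bit (foreground = 255)."""
    path = os.fspath(path)
    ext = os.path.splitext(path)[1].lower()
    if ext in _LOSSY_EXTENSIONS:
        raise FormatError(f"refusing to write mask to lossy format {ext!r}; use PNG/TIFF")
    arr = (mask.pixels * 255).astype(np.uint8)
    try:
        iio.imwrite(path, arr)
    except OSError:
        raise
    except Exception as exc:
        raise OSError(f"cannot write mask file {path!r}: {exc}") from exc
    return path


def read_mask(path: str | os.PathLike) -> BinaryMask:
    """Read a mask file; any nonzero pixel maps to foreground."""
    img = read_image(path)
    plane = img.pixels.max(axis=2)
    return BinaryMask((plane > 0).astype(np.uint8))


def rgb_to_hsv(image: RasterImage) -> RasterImage:
    """Convert an RGB/BGR image to HSV.

    H is returned in half-degree units ``[0, 180)``; S and V are scaled to
    ``[0, 255]``.  Planes are floats, so the inverse transform reproduces the
    input to within quantization.
    """
    if image.channel_order not in ("RGB", "BGR"):
        raise SemanticError(
            f"rgb_to_hsv needs an RGB or BGR image, got {image.channel_order}"
        )
    rgb = image.pixels.astype(np.float64)
    if image.channel_order == "BGR":
        rgb = rgb[:, :, ::-1]
    hsv01 = _skcolor.rgb2hsv(rgb / 255.0)
    out = np.empty_like(hsv01)
    out[..., 0] = np.mod(hsv01[..., 0], 1.0) * 180.0
    out[..., 1] = hsv01[..., 1] * 255.0
    out[..., 2] = hsv01[..., 2] * 255.0
    # guard against 180.0 from rounding at the hue wrap
    out[..., 0] = np.where(out[..., 0] >= 180.0, 0.0, out[..., 0])
    return RasterImage(out, "HSV")


def hsv_to_rgb(image: RasterImage) -> RasterImage:
    """Inverse of :func:`rgb_to_hsv`; returns float RGB in ``[0, 255]``."""
    if image.channel_order != "HSV":
        raise SemanticError(f"hsv_to_rgb needs an HSV image, got {image.channel_order}")
    hsv01 = np.empty_like(image.pixels, dtype=np.float64)
    hsv01[..., 0] = image.pixels[..., 0] / 180.0
    hsv01[..., 1] = image.pixels[..., 1] / 255.0
    hsv01[..., 2] = image.pixels[..., 2] / 255.0
    rgb = np.clip(_skcolor.hsv2rgb(hsv01) * 255.0, 0.0, 255.0)
    return RasterImage(rgb, "RGB")


def extract_channel(image: RasterImage, channel: str) -> ChannelImage:
    """Return one plane of *image* unmodified (as a copy)."""
    index = _CHANNEL_INDEX[image.channel_order]
    if channel not in index:
        raise SemanticError(
            f"channel {channel!r} not present in a {image.channel_order} image"
        )
    return ChannelImage(image.pixels[:, :, index[channel]].copy(), channel)
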