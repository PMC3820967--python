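"""Gradient images in Lab color space.

The measures downstream (complexity, self-similarity, anisotropy) all operate
on a single fused gradient image: the input is converted to Lab, oriented
luminance gradients are computed per channel with a centered-difference
kernel, and for every pixel the channel with the strongest gradient supplies
both the gradient strength and its orientation.  Images are first reduced to
a fixed pixel budget by isotropic bicubic scaling so that the measures, which
depend on resolution, are comparable across images.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from PIL import Image
from skimage import color as _skcolor
from skimage.transform import resize as _skresize

__all__ = [
    "RasterImage",
    "GradientField",
    "load_image",
    "to_lab",
    "gradient_field",
    "resize_to_budget",
    "DEFAULT_PIXEL_BUDGET",
    "CHANNEL_NAMES",
]

#: Default pixel budget used throughout the pipeline (H * W after resizing).
DEFAULT_PIXEL_BUDGET = 1_000_000

#: Reduced budget used when comparing reproductions of differing provenance
#: (halftone dots in print scans alias at the full budget).
REPRODUCTION_PIXEL_BUDGET = 100_000

#: Channel labels for the fused gradient field, indexed by channel axis.
CHANNEL_NAMES = ("L", "a", "b")

_MIN_SIDE = 8  # pyramid levels up to 4 need 2^4-divisible-ish sides


@dataclass(frozen=True)
class RasterImage:
    """An in-memory raster image with an explicit color-space tag.

    ``pixels`` is always H x W x 3 float64; grayscale inputs are promoted by
    channel replication.  sRGB images hold values in [0, 1]; Lab images hold
    L in [0, 100] and signed a/b.
    """

    pixels: np.ndarray
    color_space: str = "sRGB"

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim == 2:
            px = np.repeat(px[:, :, None], 3, axis=2)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"expected HxWx3 pixels, got shape {px.shape}")
        if px.shape[0] < _MIN_SIDE or px.shape[1] < _MIN_SIDE:
            raise ValueError(
                f"image must be at least {_MIN_SIDE}x{_MIN_SIDE}, got "
                f"{px.shape[0]}x{px.shape[1]}"
            )
        bad = ~np.isfinite(px)
        if bad.any():
            r, c, ch = np.argwhere(bad)[0]
            raise ValueError(
                f"non-finite pixel value at row={r}, col={c}, channel={ch}"
            )
        if self.color_space not in ("sRGB", "Lab"):
            raise ValueError(f"unknown color space {self.color_space!r}")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def n_pixels(self) -> int:
        return self.height * self.width


@dataclass(frozen=True)
class GradientField:
    """Per-pixel fused gradient strength/orientation.

    ``strength``: non-negative magnitudes in Lab units per pixel.
    ``orientation``: angles in degrees on [0, 360); 0 where strength is 0.
    ``source_channel``: index into :data:`CHANNEL_NAMES` of the winning
    channel per pixel.
    """

    strength: np.ndarray
    orientation: np.ndarray
    source_channel: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if not (self.strength.shape == self.orientation.shape == self.source_channel.shape):
            raise ValueError("strength/orientation/source_channel shapes differ")

    @property
    def shape(self) -> tuple[int, int]:
        return self.strength.shape


def load_image(path) -> RasterImage:
    """Read a PNG/TIFF/JPEG file into an sRGB :class:`RasterImage`.

    8- and 16-bit inputs are normalized to [0, 1].  Images with an alpha
    channel are flattened over white (with a warning); palette images are
    expanded.  Embedded ICC profiles are ignored (with a warning): the
    pipeline assumes plain sRGB with a D65 white point.
    """
    with Image.open(path) as im:
        if "icc_profile" in im.info and im.info["icc_profile"]:
            warnings.warn(
                f"{path}: embedded ICC profile ignored; assuming sRGB",
                stacklevel=2,
            )
        if im.mode == "P":
            im = im.convert("RGBA" if "transparency" in im.info else "RGB")
        arr = np.asarray(im)

    if arr.dtype == np.uint8:
        arr = arr.astype(np.float64) / 255.0
    elif arr.dtype == np.uint16:
        arr = arr.astype(np.float64) / 65535.0
    elif np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(np.float64) / np.iinfo(arr.dtype).max
    else:
        arr = arr.astype(np.float64)

    if arr.ndim == 3 and arr.shape[2] in (2, 4):  # LA / RGBA
        alpha = arr[:, :, -1:]
        rgb = arr[:, :, :-1]
        if rgb.shape[2] == 1:
            rgb = np.repeat(rgb, 3, axis=2)
        warnings.warn(f"{path}: alpha channel flattened over white", stacklevel=2)
        arr = rgb * alpha + (1.0 - alpha)
    return RasterImage(arr, "sRGB")


def to_lab(img: RasterImage) -> RasterImage:
    """Convert an sRGB image (values in [0, 1]) to Lab (D65).

    Uses the standard sRGB gamma expansion -> XYZ(D65) -> CIELAB transform.
    """
    if img.color_space == "Lab":
        return img
    px = img.pixels
    if px.min() < 0.0 or px.max() > 1.0:
        raise ValueError(
            f"sRGB values outside [0,1]: range [{px.min():.4g}, {px.max():.4g}]"
        )
    return RasterImage(_skcolor.rgb2lab(px), "Lab")


def lab_to_srgb(lab_pixels: np.ndarray) -> np.ndarray:
    """Render Lab values back to sRGB in [0, 1], clipping out-of-gamut colors."""
    return np.clip(_skcolor.lab2rgb(lab_pixels), 0.0, 1.0)


def gradient_field(img: RasterImage) -> GradientField:
    """Fused oriented gradients of a Lab image.

    Per channel, x/y derivatives use the centered-difference kernel
    [-1, 0, 1]/2 (one-sided at the borders).  For each pixel the channel with
    the largest magnitude sqrt(gx^2 + gy^2) supplies both the strength and
    the orientation atan2(gy, gx) mapped to [0, 360).
    """
    if img.color_space != "Lab":
        img = to_lab(img)
    px = img.pixels
    # np.gradient: centered differences in the interior, one-sided at borders
    gy = np.gradient(px, axis=0)
    gx = np.gradient(px, axis=1)
    mag = np.hypot(gx, gy)  # H x W x 3

    winner = np.argmax(mag, axis=2)  # ties -> lowest index (L preferred)
    rows, cols = np.indices(winner.shape)
    strength = mag[rows, cols, winner]
    theta = np.degrees(np.arctan2(gy[rows, cols, winner], gx[rows, cols, winner]))
    theta = np.mod(theta, 360.0)
    theta[strength == 0.0] = 0.0
    return GradientField(strength, theta, winner.astype(np.int8))


def resize_to_budget(
    img: RasterImage,
    budget: int = DEFAULT_PIXEL_BUDGET,
    *,
    allow_upsample: bool = False,
) -> RasterImage:
    """Isotropically rescale so that H*W lands as close to ``budget`` as
    integer rounding allows, using bicubic interpolation.

    Aspect ratio is preserved to within one pixel per side.  An image already
    at (or, without ``allow_upsample``, below) the budget is returned
    unchanged; upsampling a smaller image requires ``allow_upsample=True``.
    """
    if budget < 64:
        raise ValueError(f"pixel budget must be >= 64, got {budget}")
    n = img.n_pixels
    s = math.sqrt(budget / n)
    h2 = max(_MIN_SIDE, round(img.height * s))
    w2 = max(_MIN_SIDE, round(img.width * s))
    if (h2, w2) == (img.height, img.width):
        return img  # already as close to the budget as rounding allows
    if n < budget and not allow_upsample:
        raise ValueError(
            f"image has {n} pixels, below the budget of {budget}; "
            "pass allow_upsample=True to upsample"
        )
    out = _skresize(
        img.pixels,
        (h2, w2),
        order=3,
        mode="reflect",
        anti_aliasing=s < 1.0,
        preserve_range=True,
    )
    if img.color_space == "sRGB":
        out = np.clip(out, 0.0, 1.0)
    return RasterImage(out, img.color_space)
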