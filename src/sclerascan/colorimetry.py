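"""Color handling: decoding, illuminant compensation, denoising, RGB↔HSL.

The scleral-yellowing statistic downstream is a pure function of hue, so
this module's job is to deliver a hue channel that is as independent of
the capture illuminant as possible:

1. decode 8-bit sRGB (JPEG/PNG, EXIF orientation honoured);
2. estimate the illuminant with a Minkowski-norm color-constancy method
   (gray-world ``p=1`` or shades-of-gray, default ``p=6``) and divide it
   out with a von Kries diagonal transform *in linear RGB*;
3. optionally median-filter to suppress sensor speckle and eyelash salt;
4. convert to bi-conical (double-hexcone) HSL, hue in degrees.

The commercial compensation algorithm used in the original clinical
study is proprietary and undescribed; the Minkowski-norm estimators here
are standard, documented stand-ins with the same stated goal (color
measurements independent of the ambient light source).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image, ImageOps, UnidentifiedImageError
from scipy import ndimage

from .errors import (
    DegenerateInputError,
    ImageFormatError,
    ImageReadError,
    ParameterError,
)

__all__ = [
    "IlluminantGains",
    "HslImage",
    "read_image",
    "estimate_illuminant",
    "compensate_illumination",
    "denoise",
    "rgb_to_hsl",
    "hsl_to_rgb",
    "srgb_to_linear",
    "linear_to_srgb",
]

#: Pixel grids are plain ``uint8`` arrays of shape (H, W, 3); a dedicated
#: wrapper class would add nothing over numpy here.
RgbImage = np.ndarray


@dataclass(frozen=True)
class IlluminantGains:
    """Per-channel von Kries gains, normalized to geometric mean 1."""

    gains: np.ndarray  # shape (3,), strictly positive

    def __post_init__(self):
        g = np.asarray(self.gains, dtype=float)
        if g.shape != (3,) or not np.all(np.isfinite(g)) or np.any(g <= 0):
            raise ParameterError(f"gains must be 3 positive finite numbers, got {self.gains!r}")
        object.__setattr__(self, "gains", g)

    @classmethod
    def identity(cls) -> "IlluminantGains":
        return cls(np.ones(3))


@dataclass(frozen=True)
class HslImage:
    """Per-pixel hue (degrees, [0, 360)), saturation and lightness ([0, 1]).

    ``chromatic_mask`` is False exactly where ``saturation == 0`` — hue is
    undefined for achromatic pixels and is stored as 0 there by convention.
    """

    hue: np.ndarray
    saturation: np.ndarray
    lightness: np.ndarray
    chromatic_mask: np.ndarray

    @property
    def shape(self) -> tuple:
        return self.hue.shape


def _validate_rgb(img: np.ndarray, name: str = "img") -> np.ndarray:
    arr = np.asarray(img)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ParameterError(f"{name} must have shape (H, W, 3), got {arr.shape}")
    if arr.shape[0] < 1 or arr.shape[1] < 1:
        raise ParameterError(f"{name} must be at least 1x1")
    if arr.dtype != np.uint8:
        raise ParameterError(f"{name} must be uint8 sRGB, got dtype {arr.dtype}")
    return arr


# ---------------------------------------------------------------------------
# I/O


def read_image(path) -> RgbImage:
    """Decode a JPEG or PNG file into an 8-bit sRGB pixel grid.

    EXIF orientation is applied. Palette and RGBA content is flattened to
    RGB; 16-bit content is rescaled to 8 bits with a warning; grayscale or
    CMYK content raises :class:`ImageFormatError`.
    """
    path = Path(path)
    if not path.exists():
        raise ImageReadError(f"image file does not exist: {path}")
    try:
        with Image.open(path) as im:
            im.load()
            im = ImageOps.exif_transpose(im)
            mode = im.mode
            if mode in ("I", "I;16", "I;16B", "I;16L"):
                arr = np.asarray(im)
                warnings.warn(
                    f"{path}: {mode} content rescaled from 16-bit to 8-bit", stacklevel=2
                )
                arr8 = np.clip(np.round(arr / 257.0), 0, 255).astype(np.uint8)
                im = Image.fromarray(arr8)
                mode = im.mode
            if mode == "RGB":
                pass
            elif mode in ("RGBA", "P", "LA"):
                im = im.convert("RGB")
            else:
                raise ImageFormatError(f"{path}: unsupported mode {mode!r}, need 8-bit RGB")
            return np.asarray(im, dtype=np.uint8)
    except UnidentifiedImageError as exc:
        raise ImageFormatError(f"{path}: not a decodable JPEG/PNG image") from exc
    except OSError as exc:
        raise ImageReadError(f"{path}: failed to read image ({exc})") from exc


# ---------------------------------------------------------------------------
# sRGB transfer function (IEC 61966-2-1)


def srgb_to_linear(u: np.ndarray) -> np.ndarray:
    """sRGB electro-optical transfer: encoded [0, 1] -> linear [0, 1]."""
    u = np.asarray(u, dtype=np.float64)
    return np.where(u <= 0.04045, u / 12.92, ((u + 0.055) / 1.055) ** 2.4)


def linear_to_srgb(v: np.ndarray) -> np.ndarray:
    """Inverse sRGB transfer: linear [0, 1] -> encoded [0, 1]."""
    v = np.asarray(v, dtype=np.float64)
    return np.where(v <= 0.0031308, 12.92 * v, 1.055 * np.power(v, 1 / 2.4) - 0.055)


# ---------------------------------------------------------------------------
# Illuminant estimation / compensation


def estimate_illuminant(
    img: RgbImage, method: str = "shades_of_gray", minkowski_p: float = 6.0
) -> IlluminantGains:
    """Estimate von Kries gains that neutralize the scene illuminant.

    Gains are proportional to the inverse per-channel Minkowski-``p`` mean
    of the linearized image (``p=1`` is gray-world), normalized so their
    geometric mean is 1. Both estimators assume the scene's average (or
    p-norm average) reflectance is achromatic.
    """
    arr = _validate_rgb(img)
    if method not in ("gray_world", "shades_of_gray"):
        raise ParameterError(f"unknown method {method!r}")
    if method == "gray_world":
        p = 1.0
    else:
        p = float(minkowski_p)
        if not np.isfinite(p) or p < 1:
            raise ParameterError(f"minkowski_p must be >= 1, got {minkowski_p}")
    lin = srgb_to_linear(arr / 255.0)
    if p == 1.0:
        m = lin.mean(axis=(0, 1))
    else:
        m = np.power(np.power(lin, p).mean(axis=(0, 1)), 1.0 / p)
    if np.any(m <= 0):
        raise DegenerateInputError(
            "cannot estimate illuminant: at least one channel is identically zero"
        )
    g = 1.0 / m
    g = g / np.prod(g) ** (1.0 / 3.0)
    return IlluminantGains(g)


def compensate_illumination(img: RgbImage, gains: IlluminantGains) -> RgbImage:
    """Apply a von Kries diagonal correction in linear RGB.

    Decode sRGB, scale each channel by its gain, clip to gamut, re-encode
    to 8-bit sRGB. Dimensions are preserved.
    """
    arr = _validate_rgb(img)
    lin = srgb_to_linear(arr / 255.0) * gains.gains
    out = linear_to_srgb(np.clip(lin, 0.0, 1.0)) * 255.0
    return np.clip(np.round(out), 0, 255).astype(np.uint8)


def denoise(img: RgbImage, kernel: int = 3) -> RgbImage:
    """Per-channel median filter; ``kernel=1`` is the identity."""
    arr = _validate_rgb(img)
    k = int(kernel)
    if k < 1 or k % 2 == 0:
        raise ParameterError(f"kernel must be an odd positive integer, got {kernel}")
    if k == 1:
        return arr.copy()
    return ndimage.median_filter(arr, size=(k, k, 1))


# ---------------------------------------------------------------------------
# HSL conversion (double-hexcone / bi-conical model)


def rgb_to_hsl(img: RgbImage) -> HslImage:
    """Convert 8-bit sRGB to bi-conical HSL.

    L = (max+min)/2; S = (max−min)/(1−|2L−1|) for chromatic pixels; H is
    the standard hexagonal hue angle in degrees with red at 0° and yellow
    at 60°. Achromatic pixels (max == min) get S = 0, H = 0 and a False
    entry in the chromatic mask.
    """
    arr = _validate_rgb(img)
    u = arr / 255.0
    r, g, b = u[..., 0], u[..., 1], u[..., 2]
    mx = u.max(axis=-1)
    mn = u.min(axis=-1)
    c = mx - mn
    lightness = (mx + mn) / 2.0
    chromatic = c > 0

    saturation = np.zeros_like(lightness)
    denom = 1.0 - np.abs(2.0 * lightness - 1.0)
    np.divide(c, denom, out=saturation, where=chromatic)

    hue = np.zeros_like(lightness)
    safe_c = np.where(chromatic, c, 1.0)
    m_r = chromatic & (mx == r)
    m_g = chromatic & (mx == g) & ~m_r
    m_b = chromatic & ~m_r & ~m_g
    hp = np.zeros_like(lightness)
    hp[m_r] = ((g - b)[m_r] / safe_c[m_r]) % 6.0
    hp[m_g] = (b - r)[m_g] / safe_c[m_g] + 2.0
    hp[m_b] = (r - g)[m_b] / safe_c[m_b] + 4.0
    hue = (hp * 60.0) % 360.0
    hue[~chromatic] = 0.0
    return HslImage(hue=hue, saturation=saturation, lightness=lightness, chromatic_mask=chromatic)


def hsl_to_rgb(hue, saturation, lightness) -> np.ndarray:
    """Inverse HSL transform; returns float sRGB-encoded values in [0, 1].

    Accepts scalars or broadcastable arrays; hue in degrees.
    """
    h = (np.asarray(hue, dtype=np.float64) % 360.0) / 60.0
    s = np.asarray(saturation, dtype=np.float64)
    l = np.asarray(lightness, dtype=np.float64)
    h, s, l = np.broadcast_arrays(h, s, l)
    c = (1.0 - np.abs(2.0 * l - 1.0)) * s
    x = c * (1.0 - np.abs(h % 2.0 - 1.0))
    m = l - c / 2.0
    zeros = np.zeros_like(c)
    sext = np.floor(h).astype(int) % 6
    r1 = np.choose(sext, [c, x, zeros, zeros, x, c])
    g1 = np.choose(sext, [x, c, c, x, zeros, zeros])
    b1 = np.choose(sext, [zeros, zeros, x, c, c, x])
    return np.clip(np.stack([r1 + m, g1 + m, b1 + m], axis=-1), 0.0, 1.0)
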