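"""Color representations of single-seed photographs.

A seed photograph is analyzed in three color spaces at once:

* **RGB** — the native 8-bit camera channels;
* **CIELAB** — perceptual luminance ``L*`` (0-100) and chroma axes
  ``a*`` (green-red) and ``b*`` (blue-yellow), computed under the sRGB
  decoding, D65 white point and 2 degree observer;
* **HSI** — hue in degrees, saturation in [0, 1] and intensity
  ``I = (R+G+B)/3`` on the 0-255 scale, by the classical arccos hue
  formula.

Per-channel foreground statistics (mean and population SD for each of
the nine channels) form the chromaticity block of the feature table; the
hue mean is circular so that hues straddling 0/360 degrees average
correctly.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image, UnidentifiedImageError
from skimage import color as skcolor

__all__ = [
    "SeedImage",
    "ColorFeatures",
    "COLOR_CHANNELS",
    "read_image",
    "rgb_to_lab",
    "rgb_to_hsi",
    "luminance",
    "color_features",
]

#: canonical channel order of the 9 chromaticity categories
COLOR_CHANNELS = ("R", "G", "B", "Lstar", "astar", "bstar", "H", "S", "I")


@dataclass
class SeedImage:
    """An RGB raster of one seed, with an optional foreground mask.

    ``pixels`` is H x W x 3 uint8 in RGB channel order. ``mask``, when
    present, is a same-shape boolean foreground indicator (True = seed).
    """

    pixels: np.ndarray
    mask: np.ndarray | None = None
    label: str | None = None
    sample_id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"pixels must be H x W x 3, got shape {px.shape}")
        if px.dtype != np.uint8:
            arr = np.asarray(px, dtype=np.float64)
            if arr.min() < 0 or arr.max() > 255:
                raise ValueError("pixel values must lie in 0..255")
            px = np.round(arr).astype(np.uint8)
        self.pixels = px
        if self.mask is not None:
            m = np.asarray(self.mask).astype(bool)
            if m.shape != px.shape[:2]:
                raise ValueError(
                    f"mask shape {m.shape} does not match image {px.shape[:2]}"
                )
            self.mask = m

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


def _pixels(img) -> np.ndarray:
    """Accept a SeedImage or a bare H x W x 3 array."""
    if isinstance(img, SeedImage):
        return img.pixels
    return SeedImage(pixels=np.asarray(img)).pixels


def read_image(path) -> SeedImage:
    """Load a PNG/JPEG/TIFF photograph as an 8-bit RGB :class:`SeedImage`.

    16-bit grayscale rasters are rescaled to 8 bits; non-RGB modes
    (grayscale, palette, RGBA) are converted with a warning. The decoded
    array is always in RGB channel order regardless of on-disk layout.
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            im.load()
            mode = im.mode
            if mode == "RGB":
                pixels = np.asarray(im, dtype=np.uint8)
            elif mode in ("I;16", "I;16B", "I;16L", "I"):
                warnings.warn(
                    f"{path.name}: 16-bit grayscale input converted to 8-bit RGB"
                )
                arr = np.asarray(im, dtype=np.float64)
                g8 = np.clip(np.round(arr / 257.0), 0, 255).astype(np.uint8)
                pixels = np.stack([g8, g8, g8], axis=-1)
            else:
                warnings.warn(f"{path.name}: image mode {mode!r} converted to RGB")
                pixels = np.asarray(im.convert("RGB"), dtype=np.uint8)
    except (UnidentifiedImageError, OSError) as exc:
        raise OSError(f"cannot read image file {path}: {exc}") from exc
    return SeedImage(pixels=pixels, sample_id=path.stem)


def rgb_to_lab(img) -> np.ndarray:
    """CIELAB raster (L* 0-100, a*/b* signed) of an sRGB image.

    Uses the standard sRGB piecewise gamma decoding, the D65 white point
    and the 2 degree observer.
    """
    return skcolor.rgb2lab(_pixels(img) / 255.0)


def rgb_to_hsi(img) -> np.ndarray:
    """HSI raster: hue in degrees [0, 360), saturation [0, 1], intensity 0-255.

    Conventions for degenerate pixels: S = 0 when R+G+B = 0 (black) and
    H = 0 whenever S = 0 (achromatic), so gray pixels never produce NaN.
    """
    rgb = _pixels(img).astype(np.float64)
    r, g, b = rgb[..., 0], rgb[..., 1], rgb[..., 2]
    total = r + g + b
    intensity = total / 3.0

    safe_total = np.where(total > 0, total, 1.0)
    sat = np.where(total > 0, 1.0 - 3.0 * np.minimum(np.minimum(r, g), b) / safe_total, 0.0)

    num = 0.5 * ((r - g) + (r - b))
    den = np.sqrt((r - g) ** 2 + (r - b) * (g - b))
    cos_arg = np.where(den > 0, num / np.where(den > 0, den, 1.0), 1.0)
    theta = np.degrees(np.arccos(np.clip(cos_arg, -1.0, 1.0)))
    hue = np.where(b > g, 360.0 - theta, theta)
    hue = np.where(sat <= 0, 0.0, hue) % 360.0
    return np.stack([hue, sat, intensity], axis=-1)


def luminance(img) -> np.ndarray:
    """Rec.601 luma 0.299 R + 0.587 G + 0.114 B as a float raster."""
    rgb = _pixels(img).astype(np.float64)
    return 0.299 * rgb[..., 0] + 0.587 * rgb[..., 1] + 0.114 * rgb[..., 2]


@dataclass
class ColorFeatures:
    """Foreground mean and population SD of the 9 chromaticity channels."""

    mean_R: float
    mean_G: float
    mean_B: float
    mean_Lstar: float
    mean_astar: float
    mean_bstar: float
    mean_H: float
    mean_S: float
    mean_I: float
    sd_R: float
    sd_G: float
    sd_B: float
    sd_Lstar: float
    sd_astar: float
    sd_bstar: float
    sd_H: float
    sd_S: float
    sd_I: float

    def to_dict(self, include_sd: bool = True) -> dict[str, float]:
        out = {f"mean_{c}": getattr(self, f"mean_{c}") for c in COLOR_CHANNELS}
        if include_sd:
            out.update({f"sd_{c}": getattr(self, f"sd_{c}") for c in COLOR_CHANNELS})
        return out


def _circular_stats(deg: np.ndarray) -> tuple[float, float]:
    """Circular mean (degrees in [0, 360)) and circular SD of hue angles."""
    rad = np.radians(deg)
    c = float(np.mean(np.cos(rad)))
    s = float(np.mean(np.sin(rad)))
    mean = math.degrees(math.atan2(s, c)) % 360.0
    rbar = min(math.hypot(c, s), 1.0)
    if rbar <= 0:
        sd = 180.0  # uniform hue: report a large, finite spread
    else:
        sd = math.degrees(math.sqrt(max(-2.0 * math.log(rbar), 0.0)))
    return mean, sd


def color_features(img, mask: np.ndarray | None = None) -> ColorFeatures:
    """Per-channel statistics over the foreground of one seed image.

    ``mask`` overrides ``img.mask``; it must select at least one pixel.
    All SDs are population (divide by n) SDs; the hue mean/SD are
    circular.
    """
    if mask is None and isinstance(img, SeedImage):
        mask = img.mask
    if mask is None:
        raise ValueError("color_features requires a foreground mask")
    mask = np.asarray(mask).astype(bool)
    px = _pixels(img)
    if mask.shape != px.shape[:2]:
        raise ValueError("mask shape does not match image")
    if not mask.any():
        raise ValueError("mask selects no foreground pixels")

    rgb = px.astype(np.float64)
    lab = rgb_to_lab(px)
    hsi = rgb_to_hsi(px)

    values: dict[str, float] = {}
    planes = {
        "R": rgb[..., 0], "G": rgb[..., 1], "B": rgb[..., 2],
        "Lstar": lab[..., 0], "astar": lab[..., 1], "bstar": lab[..., 2],
        "S": hsi[..., 1], "I": hsi[..., 2],
    }
    for name, plane in planes.items():
        fg = plane[mask]
        values[f"mean_{name}"] = float(fg.mean())
        values[f"sd_{name}"] = float(fg.std())  # population SD
    hmean, hsd = _circular_stats(hsi[..., 0][mask])
    values["mean_H"] = hmean
    values["sd_H"] = hsd
    return ColorFeatures(**values)
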