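"""Otsu thresholding and seed-foreground extraction.

The binarization engine behind both the plain seed mask and the fire/ice
foreground charts. Otsu's threshold is the exhaustive argmax of the
between-class variance w0*w1*(mu0 - mu1)^2 over all 256 candidate cut
points, with ties broken toward the smallest threshold and pixels
strictly above the threshold taken as the bright class. The raw binary
image is cleaned by keeping the largest 8-connected component and
filling its holes, giving one solid seed region.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import measure

from .errors import DegenerateInputError
from .imaging import SeedImage, luminance

__all__ = ["OtsuResult", "otsu_threshold", "clean_mask", "extract_foreground"]


@dataclass
class OtsuResult:
    threshold: int  # pixels > threshold are the bright class
    between_class_variance: float


def _as_u8(gray) -> np.ndarray:
    g = np.asarray(gray)
    if g.dtype == np.uint8:
        return g
    return np.clip(np.round(g.astype(np.float64)), 0, 255).astype(np.uint8)


def otsu_threshold(gray) -> OtsuResult:
    """Exhaustive Otsu threshold of an 8-bit grayscale raster.

    Raises :class:`DegenerateInputError` for a constant image, where no
    cut point separates two classes.
    """
    g = _as_u8(gray)
    hist = np.bincount(g.ravel(), minlength=256).astype(np.float64)
    if np.count_nonzero(hist) < 2:
        raise DegenerateInputError(
            "constant image: Otsu thresholding needs at least two gray values"
        )
    p = hist / hist.sum()
    levels = np.arange(256, dtype=np.float64)
    w0 = np.cumsum(p)                 # weight of the class <= t
    m0 = np.cumsum(p * levels)        # partial first moment
    mu = m0[-1]
    w1 = 1.0 - w0
    with np.errstate(invalid="ignore", divide="ignore"):
        mu0 = np.where(w0 > 0, m0 / w0, 0.0)
        mu1 = np.where(w1 > 0, (mu - m0) / w1, 0.0)
    sigma_b = w0 * w1 * (mu0 - mu1) ** 2
    t = int(np.argmax(sigma_b))       # first occurrence = smallest threshold
    return OtsuResult(threshold=t, between_class_variance=float(sigma_b[t]))


def clean_mask(mask: np.ndarray) -> np.ndarray:
    """Keep the largest 8-connected component and fill its holes."""
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        return mask
    labels = measure.label(mask, connectivity=2)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    largest = labels == int(np.argmax(counts))
    return ndi.binary_fill_holes(largest)


def extract_foreground(img: SeedImage) -> np.ndarray:
    """Boolean seed mask from the Rec.601 grayscale of an RGB image.

    Otsu-binarizes the grayscale; the class with the higher mean
    luminance is the seed candidate (staging puts the seed on a
    contrasting darker background), then the mask is cleaned to a single
    hole-free component.
    """
    g = _as_u8(luminance(img))
    res = otsu_threshold(g)
    bright = g > res.threshold
    # polarity check: foreground is the class with the larger mean luma
    if float(g[bright].mean()) < float(g[~bright].mean()):
        bright = ~bright
    return clean_mask(bright)
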