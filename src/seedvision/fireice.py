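"""Fire-ice feature fusion: two scalars summarizing color and texture.

The fusion step collapses the 31-dimensional feature vector of a seed
into two interpretable scalars:

* the **fire value** fuses the nine chromaticity channels. Every pixel
  receives a score in [0, 1] — the (optionally weighted) mean of the
  nine channels after each is normalized to [0, 1] by its natural range
  (R, G, B, I by /255; L* by /100; a*, b* by (v+128)/255; H by /360;
  S as is). The per-pixel score map is Otsu-binarized to yield the fire
  foreground, and the fire value is the mean score over that
  foreground. The score is monotone in brightness, so brighter seeds
  score higher;

* the **ice value** fuses the 22 texture categories into one bounded
  scalar: the mean of contrast/(levels-1)^2, dissimilarity/(levels-1),
  homogeneity, energy, ASM, (correlation+1)/2 and the sixteen
  self-normalized Law's ratios e_k / (e_k + e_L5L5 + eps). The ratio
  form puts the unbounded energies on a per-image [0, 1) scale without
  batch-dependent standardization, so a single image has a well-defined
  ice value.

The paired binary fire/ice foreground rasters form the fire-ice chart
of a sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateInputError
from .imaging import SeedImage, luminance, rgb_to_hsi, rgb_to_lab, _pixels
from .segmentation import clean_mask, extract_foreground, otsu_threshold
from .texture import LAWS_NAMES, _laws_energy_maps, glcm_features_avg, laws_features

__all__ = [
    "FireIceValues",
    "FireIceChart",
    "fire_score_map",
    "extract_fire_foreground",
    "fire_value",
    "ice_score_map",
    "extract_ice_foreground",
    "ice_value",
    "fireice_chart",
    "reduce_dataset",
]

logger = logging.getLogger(__name__)

_EPS = 1e-12


@dataclass
class FireIceValues:
    fire: float
    ice: float
    sample_id: str = ""
    label: str | None = None


@dataclass
class FireIceChart:
    fire_fg: np.ndarray
    ice_fg: np.ndarray


def fire_score_map(img, weights: Sequence[float] | None = None) -> np.ndarray:
    """Per-pixel fused color score in [0, 1].

    ``weights`` (channel order R, G, B, L*, a*, b*, H, S, I) defaults to
    uniform; they are normalized to sum to 1.
    """
    rgb = _pixels(img).astype(np.float64) / 255.0
    lab = rgb_to_lab(img)
    hsi = rgb_to_hsi(img)
    channels = np.stack([
        rgb[..., 0],
        rgb[..., 1],
        rgb[..., 2],
        lab[..., 0] / 100.0,
        (lab[..., 1] + 128.0) / 255.0,
        (lab[..., 2] + 128.0) / 255.0,
        hsi[..., 0] / 360.0,
        hsi[..., 1],
        hsi[..., 2] / 255.0,
    ])
    if weights is None:
        return channels.mean(axis=0)
    w = np.asarray(weights, dtype=np.float64)
    if w.shape != (9,) or w.sum() <= 0 or (w < 0).any():
        raise ValueError("weights must be 9 non-negative values with positive sum")
    w = w / w.sum()
    return np.tensordot(w, channels, axes=1)


def extract_fire_foreground(img, weights: Sequence[float] | None = None) -> np.ndarray:
    """Binary fire foreground: Otsu on the 0-255-scaled fire score map."""
    score = np.clip(np.round(fire_score_map(img, weights) * 255.0), 0, 255)
    res = otsu_threshold(score.astype(np.uint8))
    return clean_mask(score > res.threshold)


def fire_value(img, foreground: np.ndarray | None = None,
               weights: Sequence[float] | None = None) -> float:
    """Mean fire score over the fire foreground."""
    if foreground is None:
        foreground = extract_fire_foreground(img, weights)
    foreground = np.asarray(foreground).astype(bool)
    if not foreground.any():
        raise DegenerateInputError("empty fire foreground")
    return float(fire_score_map(img, weights)[foreground].mean())


def ice_score_map(gray, window: int = 15) -> np.ndarray:
    """Min-max rescaled sum of the 15 zero-sum-kernel Law's energy maps.

    L5L5 is excluded: it is a luminance channel, not a texture one.
    """
    maps = _laws_energy_maps(gray, window=window)
    total = np.zeros_like(maps["L5E5"])
    for name in LAWS_NAMES:
        if name != "L5L5":
            total += maps[name]
    lo, hi = float(total.min()), float(total.max())
    if hi - lo <= 0:
        raise DegenerateInputError("flat texture energy: constant image")
    return (total - lo) / (hi - lo)


def extract_ice_foreground(gray, window: int = 15) -> np.ndarray:
    """Binary ice foreground: Otsu on the 0-255-scaled ice score map."""
    score = np.clip(np.round(ice_score_map(gray, window) * 255.0), 0, 255)
    res = otsu_threshold(score.astype(np.uint8))
    return clean_mask(score > res.threshold)


def ice_value(gray, mask, levels: int = 32, distance: int = 1,
              angles=(0, 45, 90, 135), window: int = 15,
              erosion: int = 7) -> float:
    """Fused texture scalar in [0, 1] over the foreground ``mask``.

    Mean of 22 bounded terms: the six normalized GLCM statistics and the
    sixteen Law's ratios (L5L5's own ratio is ~0.5 for textured regions
    and 0 for flat ones, keeping the 22-category accounting intact).
    """
    g = glcm_features_avg(gray, mask, levels=levels, distance=distance,
                          angles=angles)
    laws = laws_features(gray, mask, window=window, erosion=erosion)
    e_l5l5 = laws["L5L5"]
    terms = [
        g.contrast / (levels - 1) ** 2,
        g.dissimilarity / (levels - 1),
        g.homogeneity,
        g.energy,
        g.ASM,
        (g.correlation + 1.0) / 2.0,
    ]
    terms += [laws[name] / (laws[name] + e_l5l5 + _EPS) for name in LAWS_NAMES]
    return float(sum(terms) / 22.0)


def fireice_chart(img, weights: Sequence[float] | None = None,
                  window: int = 15) -> FireIceChart:
    """Paired binary fire/ice foregrounds of one image."""
    return FireIceChart(
        fire_fg=extract_fire_foreground(img, weights),
        ice_fg=extract_ice_foreground(luminance(img), window=window),
    )


def reduce_dataset(images: Iterable[SeedImage],
                   weights: Sequence[float] | None = None,
                   levels: int = 32, distance: int = 1,
                   angles=(0, 45, 90, 135), window: int = 15,
                   erosion: int = 7,
                   mask_source: str = "segment") -> pd.DataFrame:
    """Fire/ice table (sample_id, label, fire, ice), one row per image.

    ``mask_source``: ``"segment"`` recomputes the seed mask with the
    Otsu pipeline (default, self-contained); ``"provided"`` uses each
    image's own mask. Samples whose fusion fails (e.g. a degenerate
    image) are skipped with a logged warning.
    """
    rows = []
    for img in images:
        try:
            if mask_source == "provided" and img.mask is not None:
                mask = img.mask
            else:
                mask = extract_foreground(img)
            fire = fire_value(img, weights=weights)
            ice = ice_value(luminance(img), mask, levels=levels,
                            distance=distance, angles=angles,
                            window=window, erosion=erosion)
        except (DegenerateInputError, ValueError, OSError) as exc:
            logger.warning("skipping sample %r: %s", img.sample_id, exc)
            continue
        rows.append({"sample_id": img.sample_id, "label": img.label,
                     "fire": fire, "ice": ice})
    return pd.DataFrame(rows, columns=["sample_id", "label", "fire", "ice"])
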