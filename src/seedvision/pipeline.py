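"""Feature-table assembly: from images (or an image directory) to CSV-ready
DataFrames.

One row per seed image; the canonical raw table has a ``sample_id`` and
``label`` column followed by the 9 chromaticity means and the 22 texture
categories (31 features). Channel SDs can be appended as auxiliary
columns but are excluded from chemometrics by default.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

from .errors import DegenerateInputError
from .imaging import COLOR_CHANNELS, SeedImage, color_features, luminance, read_image
from .segmentation import extract_foreground
from .texture import TEXTURE_COLUMNS, texture_features

__all__ = ["COLOR_MEAN_COLUMNS", "RAW_FEATURE_COLUMNS", "load_images",
           "color_table", "texture_table", "feature_table"]

logger = logging.getLogger(__name__)

COLOR_MEAN_COLUMNS = tuple(f"mean_{c}" for c in COLOR_CHANNELS)
RAW_FEATURE_COLUMNS = COLOR_MEAN_COLUMNS + TEXTURE_COLUMNS


def load_images(images_dir: str | Path,
                manifest: pd.DataFrame | None = None) -> Iterator[SeedImage]:
    """Yield SeedImages from a directory, optionally guided by a manifest.

    Without a manifest, every ``*.png``/``*.jpg``/``*.jpeg``/``*.tif``/
    ``*.tiff`` file (mask files excluded) is read in sorted order.
    Unreadable or missing files are skipped with a logged warning.
    """
    images_dir = Path(images_dir)
    if manifest is None:
        manifest_file = images_dir / "manifest.csv"
        if manifest_file.exists():
            manifest = pd.read_csv(manifest_file)
    if manifest is not None and "path" in manifest.columns:
        entries = [(images_dir / row["path"], row.get("label"),
                    str(row["sample_id"]))
                   for _, row in manifest.iterrows()]
    else:
        exts = {".png", ".jpg", ".jpeg", ".tif", ".tiff"}
        entries = [(p, None, p.stem) for p in sorted(images_dir.iterdir())
                   if p.suffix.lower() in exts
                   and not p.stem.endswith("_mask")]
    for path, label, sid in entries:
        try:
            img = read_image(path)
        except OSError as exc:
            logger.warning("skipping %s: %s", path, exc)
            continue
        img.label = None if label is None or pd.isna(label) else str(label)
        img.sample_id = sid
        yield img


def _seed_mask(img: SeedImage, mask_source: str) -> np.ndarray:
    if mask_source == "provided" and img.mask is not None:
        return img.mask
    return extract_foreground(img)


def color_table(images: Iterable[SeedImage], include_sd: bool = True,
                mask_source: str = "segment") -> pd.DataFrame:
    """Chromaticity feature table (9 means, optionally 9 SDs) per image."""
    rows = []
    for img in images:
        try:
            mask = _seed_mask(img, mask_source)
            feats = color_features(img, mask).to_dict(include_sd=include_sd)
        except (DegenerateInputError, ValueError) as exc:
            logger.warning("skipping sample %r: %s", img.sample_id, exc)
            continue
        rows.append({"sample_id": img.sample_id, "label": img.label, **feats})
    return pd.DataFrame(rows)


def texture_table(images: Iterable[SeedImage], levels: int = 32,
                  distance: int = 1, angles=(0, 45, 90, 135),
                  window: int = 15, erosion: int = 7,
                  mask_source: str = "segment") -> pd.DataFrame:
    """The 22 texture categories per image."""
    rows = []
    for img in images:
        try:
            mask = _seed_mask(img, mask_source)
            feats = texture_features(luminance(img), mask, levels=levels,
                                     distance=distance, angles=angles,
                                     window=window, erosion=erosion)
        except (DegenerateInputError, ValueError) as exc:
            logger.warning("skipping sample %r: %s", img.sample_id, exc)
            continue
        rows.append({"sample_id": img.sample_id, "label": img.label, **feats})
    return pd.DataFrame(rows)


def feature_table(images: Iterable[SeedImage], include_sd: bool = False,
                  levels: int = 32, distance: int = 1,
                  angles=(0, 45, 90, 135), window: int = 15,
                  erosion: int = 7, mask_source: str = "segment",
                  ) -> pd.DataFrame:
    """Joined 31-feature table (9 color means + 22 texture categories).

    The seed mask is extracted once per image and shared by both feature
    families.
    """
    rows = []
    for img in images:
        try:
            mask = _seed_mask(img, mask_source)
            feats = color_features(img, mask).to_dict(include_sd=include_sd)
            feats.update(texture_features(luminance(img), mask, levels=levels,
                                          distance=distance, angles=angles,
                                          window=window, erosion=erosion))
        except (DegenerateInputError, ValueError) as exc:
            logger.warning("skipping sample %r: %s", img.sample_id, exc)
            continue
        rows.append({"sample_id": img.sample_id, "label": img.label, **feats})
    return pd.DataFrame(rows)
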