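"""Synthetic seed-image generator with class-conditional color and texture.

Photographs of the three seed classes — genuine spine-date seed
(synthZSS) and its two market substitutes (synthZMS, synthHAS) — are
not publicly deposited, so every downstream stage is
exercised on rendered stand-ins. Each image is one filled, rotated
ellipse on a dark field, colored at a class-specific CIELAB base color,
with additive band-limited noise, optional salt speckle and a mild
vertical shading gradient.

The generator's contract is ordinal, not photometric: its default class
parameters are tuned so that the *extracted* features reproduce the
documented qualitative orderings of the real material —

* brightness L*: synthHAS > synthZSS > synthZMS;
* redness a* and yellowness b*: synthZMS highest;
* GLCM contrast: synthZSS highest (sparse bright speckle);
* homogeneity / energy: synthHAS highest (smooth, low-noise surface);
* all 16 Law's texture energies: synthZMS highest (strong white noise).

Class names carry a ``synth`` prefix to mark them as synthetic stand-ins
for Ziziphi Spinosae Semen (ZSS), Ziziphi Mauritianae Semen (ZMS) and
Hovenia Acerba Semen (HAS).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage as ndi
from skimage import color as skcolor
from skimage.draw import ellipse as draw_ellipse

from .imaging import SeedImage

__all__ = ["SynthClassParams", "default_params", "generate_seed_image",
           "generate_dataset", "CLASS_NAMES"]

CLASS_NAMES = ("synthZSS", "synthZMS", "synthHAS")

#: brightness of salt-speckle pixels (classic salt: saturated white)
SPECKLE_VALUE = 255
#: background gray level and its half-range of uniform jitter
BACKGROUND_LEVEL = 30
BACKGROUND_JITTER = 5
#: half-amplitude of the vertical shading gradient (fraction of intensity)
SHADING_FRACTION = 0.08


@dataclass
class SynthClassParams:
    """Rendering parameters of one synthetic seed class."""

    name: str
    base_lab: tuple[float, float, float]   # (L*, a*, b*) of the testa
    noise_amplitude: float                 # additive noise SD, intensity units
    noise_smoothness: int                  # uniform-filter size, px (1 = white)
    speckle_density: float                 # fraction of foreground salt pixels
    ellipse_radii_range: tuple[int, int] = (55, 90)
    mottle_amplitude: float = 0.0          # coarse testa blotching, SD units
    mottle_sigma: float = 2.0              # gaussian scale of the mottle, px

    def __post_init__(self) -> None:
        l, _, _ = self.base_lab
        if not 0 <= l <= 100:
            raise ValueError("base L* must lie in [0, 100]")
        if self.noise_amplitude < 0 or self.noise_smoothness < 1:
            raise ValueError("noise amplitude must be >= 0, smoothness >= 1")
        if not 0 <= self.speckle_density < 1:
            raise ValueError("speckle density must lie in [0, 1)")


def default_params() -> list[SynthClassParams]:
    """The three pinned class parameter sets.

    The base L* ordering 65 > 48 > 38 (HAS > ZSS > ZMS) mirrors the
    documented brightness ordering of the real seeds; ZMS carries the
    largest chroma (a* 32, b* 35), the strongest white noise and a
    coarse low-frequency mottle (blotchy testa), ZSS a sparse glossy
    salt speckle over a mildly noisy coat, HAS the smoothest low-noise
    surface.

    The division of labor matters: for spatially uncorrelated texture,
    GLCM contrast at distance 1 is tied to the pixel variance, so the
    class with the top contrast would also top every texture energy.
    The sparse bright speckle concentrates ZSS's variance into large
    rare jumps (quadratic statistics such as contrast see them fully,
    mean-absolute energies much less), while ZMS's dense noise plus
    mottle dominates all 16 Law's bands including the luminance one.
    """
    return [
        SynthClassParams("synthHAS", (65.0, 18.0, 30.0), 4.0, 3, 0.00),
        SynthClassParams("synthZSS", (48.0, 25.0, 22.0), 6.0, 1, 0.02),
        SynthClassParams("synthZMS", (38.0, 32.0, 35.0), 18.0, 1, 0.00,
                         mottle_amplitude=10.0),
    ]


def _lab_to_rgb255(lab: tuple[float, float, float]) -> np.ndarray:
    rgb = skcolor.lab2rgb(np.asarray(lab, dtype=np.float64).reshape(1, 1, 3))
    return np.clip(rgb[0, 0] * 255.0, 0, 255)


def generate_seed_image(params: SynthClassParams, canvas: tuple[int, int] = (256, 256),
                        seed: int = 0, sample_id: str = "") -> tuple[SeedImage, np.ndarray]:
    """Render one seed; returns the image and its ground-truth mask.

    Deterministic for a given (params, canvas, seed). The mask is also
    attached to the returned :class:`SeedImage`.
    """
    h, w = canvas
    r_lo, r_hi = params.ellipse_radii_range
    if 2 * r_hi + 20 > min(h, w):
        raise ValueError("ellipse radii too large for the canvas")
    rng = np.random.default_rng(seed)

    img = np.empty((h, w, 3), dtype=np.float64)
    bg = rng.uniform(BACKGROUND_LEVEL - BACKGROUND_JITTER,
                     BACKGROUND_LEVEL + BACKGROUND_JITTER, size=(h, w))
    img[...] = bg[..., None]

    ra = rng.uniform(r_lo, r_hi)
    rb = rng.uniform(r_lo, r_hi)
    theta = rng.uniform(0.0, np.pi)
    cy = h / 2 + rng.uniform(-8, 8)
    cx = w / 2 + rng.uniform(-8, 8)
    rr, cc = draw_ellipse(cy, cx, ra, rb, shape=(h, w), rotation=theta)
    mask = np.zeros((h, w), dtype=bool)
    mask[rr, cc] = True

    img[mask] = _lab_to_rgb255(params.base_lab)

    if params.noise_amplitude > 0:
        noise = rng.standard_normal((h, w))
        if params.noise_smoothness > 1:
            noise = ndi.uniform_filter(noise, size=params.noise_smoothness,
                                       mode="reflect")
        sd = noise.std()
        if sd > 0:
            noise = noise / sd * params.noise_amplitude
        img[mask] += noise[mask, None]

    if params.mottle_amplitude > 0:
        mottle = ndi.gaussian_filter(rng.standard_normal((h, w)),
                                     sigma=params.mottle_sigma, mode="reflect")
        sd = mottle.std()
        if sd > 0:
            mottle = mottle / sd * params.mottle_amplitude
        img[mask] += mottle[mask, None]

    if params.speckle_density > 0:
        n_fg = int(mask.sum())
        n_salt = int(round(params.speckle_density * n_fg))
        if n_salt:
            idx = rng.choice(n_fg, size=n_salt, replace=False)
            fr, fc = np.nonzero(mask)
            img[fr[idx], fc[idx]] = SPECKLE_VALUE

    shading = np.linspace(1.0 - SHADING_FRACTION, 1.0 + SHADING_FRACTION, h)
    img *= shading[:, None, None]

    pixels = np.clip(np.round(img), 0, 255).astype(np.uint8)
    return (SeedImage(pixels=pixels, mask=mask, label=params.name,
                      sample_id=sample_id), mask)


def generate_dataset(n_per_class: int | Mapping[str, int] = 30, seed: int = 42,
                     out_dir: str | Path | None = None,
                     params: list[SynthClassParams] | None = None,
                     canvas: tuple[int, int] = (256, 256),
                     ) -> tuple[list[SeedImage], pd.DataFrame]:
    """Render a labeled dataset; optionally persist PNGs plus a manifest.

    ``n_per_class`` may be a single count or a mapping class name ->
    count (e.g. the real survey's 300/88/100 batch structure). Per-image
    seeds are drawn from the master ``seed``, so the whole dataset is
    reproducible. When ``out_dir`` is given, images, masks and a
    ``manifest.csv`` (sample_id, label, path, mask_path, true_area) are
    written there.
    """
    if params is None:
        params = default_params()
    if isinstance(n_per_class, int):
        counts = {p.name: n_per_class for p in params}
    else:
        counts = dict(n_per_class)
    for name, n in counts.items():
        if n < 1:
            raise ValueError(f"class {name!r} needs at least 1 sample")

    total = sum(counts.values())
    master = np.random.default_rng(seed)
    child_seeds = master.integers(0, 2**31 - 1, size=total)

    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)

    images: list[SeedImage] = []
    records = []
    k = 0
    for p in params:
        for i in range(counts.get(p.name, 0)):
            sid = f"{p.name}-{i + 1:03d}"
            img, mask = generate_seed_image(p, canvas=canvas,
                                            seed=int(child_seeds[k]),
                                            sample_id=sid)
            k += 1
            images.append(img)
            rec = {"sample_id": sid, "label": p.name,
                   "true_area": int(mask.sum())}
            if out_path is not None:
                img_file = out_path / f"{sid}.png"
                mask_file = out_path / f"{sid}_mask.png"
                Image.fromarray(img.pixels).save(img_file)
                Image.fromarray((mask.astype(np.uint8) * 255)).save(mask_file)
                rec["path"] = img_file.name
                rec["mask_path"] = mask_file.name
            records.append(rec)

    manifest = pd.DataFrame(records)
    if out_path is not None:
        manifest.to_csv(out_path / "manifest.csv", index=False)
    return images, manifest
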