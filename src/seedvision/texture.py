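"""Texture descriptors: GLCM statistics and Law's texture energies.

Two classical families make up the 22 texture categories per seed:

* six gray-level co-occurrence matrix (GLCM) statistics — contrast,
  dissimilarity, homogeneity, energy, correlation and ASM — computed on
  the uniformly quantized grayscale (32 levels by default) at distance 1
  and averaged over the four canonical directions 0/45/90/135 degrees.
  Only pixel pairs with both endpoints inside the foreground mask are
  counted, and the matrix is symmetrized and normalized;

* sixteen Law's texture energy measures, the mean absolute response to
  the 5x5 separable kernels built from the 1-D vectors
  L5 (level), E5 (edge), S5 (spot) and R5 (ripple), after 15x15 local
  mean removal, with energy maps smoothed by a 15x15 moving average and
  averaged over the mask eroded by 7 px to avoid boundary effects.

Conventions that the literature leaves open are pinned here:
homogeneity uses the inverse-difference form sum P/(1+|i-j|), and the
correlation of a zero-variance (single-level) matrix is defined as 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .errors import DegenerateInputError

__all__ = [
    "GLCMMatrix",
    "GLCMFeatures",
    "GLCM_FEATURE_NAMES",
    "LAWS_NAMES",
    "compute_glcm",
    "glcm_features",
    "glcm_features_avg",
    "laws_kernels",
    "laws_features",
    "texture_features",
    "TEXTURE_COLUMNS",
]

GLCM_FEATURE_NAMES = ("contrast", "dissimilarity", "homogeneity", "energy",
                      "correlation", "ASM")

_LAWS_1D = {
    "L5": np.array([1.0, 4.0, 6.0, 4.0, 1.0]),
    "E5": np.array([-1.0, -2.0, 0.0, 2.0, 1.0]),
    "S5": np.array([-1.0, 0.0, 2.0, 0.0, -1.0]),
    "R5": np.array([1.0, -4.0, 6.0, -4.0, 1.0]),
}
_LAWS_ORDER = ("L5", "E5", "S5", "R5")
#: the 16 kernel names, row vector first (L5E5 = column L5 times row E5)
LAWS_NAMES = tuple(a + b for a in _LAWS_ORDER for b in _LAWS_ORDER)

TEXTURE_COLUMNS = GLCM_FEATURE_NAMES + LAWS_NAMES

# pixel offsets (drow, dcol) at unit distance for the four GLCM directions
_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


@dataclass
class GLCMMatrix:
    """Symmetric, normalized pair-probability matrix of quantized levels."""

    P: np.ndarray
    levels: int
    distance: int
    angle: int


@dataclass
class GLCMFeatures:
    contrast: float
    dissimilarity: float
    homogeneity: float
    energy: float
    correlation: float
    ASM: float

    def to_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in GLCM_FEATURE_NAMES}


def quantize(gray, levels: int) -> np.ndarray:
    """Uniformly map 8-bit gray values 0..255 onto 0..levels-1."""
    g = np.asarray(gray)
    g = np.clip(np.round(g.astype(np.float64)), 0, 255).astype(np.int64)
    return (g * levels) // 256


def compute_glcm(gray, mask=None, levels: int = 32, distance: int = 1,
                 angle: int = 0) -> GLCMMatrix:
    """Masked GLCM at one direction and distance.

    Only pairs with both endpoints inside ``mask`` contribute; pairs are
    counted in both directions so the matrix is symmetric, and the
    result is normalized to sum to 1.
    """
    if levels < 2:
        raise ValueError("levels must be >= 2")
    if angle not in _OFFSETS:
        raise ValueError(f"angle must be one of {sorted(_OFFSETS)}, got {angle}")
    q = quantize(gray, levels)
    h, w = q.shape
    if mask is None:
        mask = np.ones((h, w), dtype=bool)
    else:
        mask = np.asarray(mask).astype(bool)

    dr, dc = (d * distance for d in _OFFSETS[angle])
    r0, r1 = max(0, -dr), h - max(0, dr)
    c0, c1 = max(0, -dc), w - max(0, dc)
    if r1 <= r0 or c1 <= c0:
        raise DegenerateInputError("image smaller than the GLCM offset")
    a = q[r0:r1, c0:c1]
    b = q[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
    valid = mask[r0:r1, c0:c1] & mask[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
    if not valid.any():
        raise DegenerateInputError("no valid pixel pair under the mask")

    counts = np.bincount(a[valid] * levels + b[valid],
                         minlength=levels * levels).astype(np.float64)
    C = counts.reshape(levels, levels)
    C = C + C.T
    P = C / C.sum()
    return GLCMMatrix(P=P, levels=levels, distance=distance, angle=angle)


def glcm_features(glcm) -> GLCMFeatures:
    """The six co-occurrence statistics of one normalized GLCM.

    ``glcm`` may be a :class:`GLCMMatrix` or a bare normalized matrix.
    """
    P = glcm.P if isinstance(glcm, GLCMMatrix) else np.asarray(glcm, dtype=np.float64)
    n = P.shape[0]
    i = np.arange(n, dtype=np.float64)[:, None]
    j = np.arange(n, dtype=np.float64)[None, :]
    diff = np.abs(i - j)

    contrast = float((P * (i - j) ** 2).sum())
    dissimilarity = float((P * diff).sum())
    homogeneity = float((P / (1.0 + diff)).sum())
    asm = float((P ** 2).sum())
    energy = float(np.sqrt(asm))

    px = P.sum(axis=1)
    mu = float((np.arange(n) * px).sum())
    var = float(((np.arange(n) - mu) ** 2 * px).sum())
    if var <= 0:
        correlation = 1.0  # single-level texture is perfectly self-correlated
    else:
        correlation = float(((P * i * j).sum() - mu * mu) / var)
    return GLCMFeatures(contrast=contrast, dissimilarity=dissimilarity,
                        homogeneity=homogeneity, energy=energy,
                        correlation=correlation, ASM=asm)


def glcm_features_avg(gray, mask=None, levels: int = 32, distance: int = 1,
                      angles=(0, 45, 90, 135)) -> GLCMFeatures:
    """GLCM features averaged over a set of directions."""
    feats = [glcm_features(compute_glcm(gray, mask, levels, distance, a))
             for a in angles]
    mean = {name: float(np.mean([f.to_dict()[name] for f in feats]))
            for name in GLCM_FEATURE_NAMES}
    return GLCMFeatures(**mean)


def laws_kernels() -> dict[str, np.ndarray]:
    """The 16 ordered 5x5 Law's kernels as outer products of L5/E5/S5/R5."""
    return {name: np.outer(_LAWS_1D[name[:2]], _LAWS_1D[name[2:]])
            for name in LAWS_NAMES}


def _laws_energy_maps(gray, window: int = 15) -> dict[str, np.ndarray]:
    """Per-kernel texture energy maps of a grayscale raster.

    Pipeline: subtract the ``window`` x ``window`` local mean, convolve
    with each kernel separably (reflect padding), take the absolute
    response and smooth it with a ``window`` x ``window`` moving
    average.
    """
    g = np.asarray(gray, dtype=np.float64)
    resid = g - ndi.uniform_filter(g, size=window, mode="reflect")
    maps = {}
    for name in LAWS_NAMES:
        resp = ndi.convolve1d(resid, _LAWS_1D[name[:2]], axis=0, mode="reflect")
        resp = ndi.convolve1d(resp, _LAWS_1D[name[2:]], axis=1, mode="reflect")
        maps[name] = ndi.uniform_filter(np.abs(resp), size=window, mode="reflect")
    return maps


def laws_features(gray, mask, window: int = 15, erosion: int = 7) -> dict[str, float]:
    """Mean texture energy per Law's kernel over the eroded foreground."""
    mask = np.asarray(mask).astype(bool)
    core = ndi.binary_erosion(mask, structure=np.ones((3, 3), bool),
                              iterations=erosion)
    if not core.any():
        raise DegenerateInputError(
            "foreground too small: empty after boundary erosion"
        )
    maps = _laws_energy_maps(gray, window=window)
    return {name: float(maps[name][core].mean()) for name in LAWS_NAMES}


def texture_features(gray, mask, levels: int = 32, distance: int = 1,
                     angles=(0, 45, 90, 135), window: int = 15,
                     erosion: int = 7) -> dict[str, float]:
    """All 22 texture categories (6 GLCM + 16 Law's) of one seed."""
    out = glcm_features_avg(gray, mask, levels, distance, angles).to_dict()
    out.update(laws_features(gray, mask, window=window, erosion=erosion))
    return out
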