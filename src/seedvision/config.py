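"""Run configuration: the pinned pipeline parameters in one place.

A :class:`RunConfig` can be loaded from a YAML file (unknown keys are
rejected) and overridden field-by-field from CLI flags. The SHA-256 hash
of the effective configuration is logged with every run so outputs can
be traced back to their exact settings.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    seed: int = 42
    n_per_class: int = 30
    canvas: tuple[int, int] = (256, 256)
    # GLCM
    glcm_levels: int = 32
    glcm_distance: int = 1
    glcm_angles: tuple[int, ...] = (0, 45, 90, 135)
    # Law's
    laws_window: int = 15
    laws_erosion: int = 7
    # fire fusion (None = uniform over the 9 channels)
    fire_weights: tuple[float, ...] | None = None
    # chemometrics
    ncomp_raw: int = 3
    ncomp_fireice: int = 2
    nperm: int = 200
    cv_folds: int = 7
    # classification
    train_fraction: float = 0.70

    def __post_init__(self) -> None:
        if self.glcm_levels < 2:
            raise ValueError("glcm_levels must be >= 2")
        if self.glcm_distance < 1:
            raise ValueError("glcm_distance must be >= 1")
        if any(a not in (0, 45, 90, 135) for a in self.glcm_angles):
            raise ValueError("glcm_angles must be drawn from {0, 45, 90, 135}")
        if self.laws_window < 3 or self.laws_window % 2 == 0:
            raise ValueError("laws_window must be an odd size >= 3")
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.fire_weights is not None and len(self.fire_weights) != 9:
            raise ValueError("fire_weights must have 9 entries")
        if self.nperm < 1 or self.cv_folds < 2:
            raise ValueError("nperm must be >= 1 and cv_folds >= 2")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ValueError("config file must hold a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {', '.join(sorted(unknown))}")
        for key in ("canvas", "glcm_angles", "fire_weights"):
            if key in data and data[key] is not None:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def digest(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]
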