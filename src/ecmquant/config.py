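"""Validated run configuration (YAML) with documented defaults.

Defaults mirror the standard acquisition/analysis settings of the
pipeline: particles below 1 µm² are excluded, the single-cell band is
±3 MAD, thickness segmentation uses 20-voxel cubes, the confocal z-step
is 0.5 µm, and channel floors/intensity cut-offs follow the stained
bacterial-biofilm settings (FITC floor 0.085, FM4-64 floor 0.07, cube
mean-intensity floor 75 A.U.).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict
from pathlib import Path

import yaml

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass
class RunConfig:
    stage: str = ""
    inputs: list = field(default_factory=list)
    out_dir: str = "results"
    seed: int = 0
    # 2-D calibration and classification
    pixel_size: float = 0.65  # µm/pixel
    min_area_um2: float = 1.0
    k: float = 3.0  # MAD multiplier
    min_seg: int = 5
    # 3-D calibration and quantification
    voxel_pitch: tuple = (0.5, 0.25, 0.25)  # (z, y, x) µm
    denoise_kernel: tuple = (5, 5, 3)  # (x, y, z) voxels
    tophat_size: int = 15  # 0 disables background subtraction
    floor_threshold: float = 0.085  # EPS (FITC) channel
    floor_threshold_cell: float = 0.07  # cell (FM4-64) channel
    cube_side: int = 20
    min_mean_intensity: float = 75.0  # A.U.

    def __post_init__(self):
        self.validate()

    def validate(self):
        if self.pixel_size <= 0:
            raise ValueError(f"pixel_size must be > 0, got {self.pixel_size}")
        if len(self.voxel_pitch) != 3 or any(p <= 0 for p in self.voxel_pitch):
            raise ValueError(f"voxel_pitch must be 3 positive values, got {self.voxel_pitch}")
        if self.min_area_um2 < 0:
            raise ValueError("min_area_um2 must be >= 0")
        if self.k <= 0:
            raise ValueError("k must be > 0")
        if self.min_seg < 2:
            raise ValueError("min_seg must be >= 2")
        if self.cube_side < 1:
            raise ValueError("cube_side must be >= 1")
        for name in ("floor_threshold", "floor_threshold_cell"):
            val = getattr(self, name)
            if not 0 <= val <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {val}")
        if len(self.denoise_kernel) != 3 or any(
            k < 1 or k % 2 == 0 for k in self.denoise_kernel
        ):
            raise ValueError("denoise_kernel must be three odd extents (x, y, z)")
        if self.tophat_size < 0:
            raise ValueError("tophat_size must be >= 0 (0 disables)")
        self.voxel_pitch = tuple(float(p) for p in self.voxel_pitch)
        self.denoise_kernel = tuple(int(k) for k in self.denoise_kernel)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["voxel_pitch"] = list(self.voxel_pitch)
        d["denoise_kernel"] = list(self.denoise_kernel)
        return d


def load_config(path) -> RunConfig:
    """Load and validate a YAML config; missing keys take defaults."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return RunConfig.from_dict(data)


def save_config(path, config: RunConfig) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
    return path
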