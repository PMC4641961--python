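"""Pipeline configuration: every tunable in one validated record.

Defaults follow the method's published constants where stated (lightness
threshold 15, 50% black-row rule, 10 extra frame rows, Gaussian filter size
15) and this package's documented choices where not (top-hat radius, hair
filter, growing tolerance, smoothing sigma, prominence floor, matching
tolerance).  Precedence: built-in defaults < config file < explicit
overrides.
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass
from pathlib import Path


class ConfigError(ValueError):
    """A configuration value is outside its permitted range."""


@dataclass(frozen=True)
class PipelineConfig:
    # black frame removal
    frame_lightness_thresh: float = 15.0
    frame_black_row_fraction: float = 0.5
    frame_extra_rows: int = 10
    # hair removal
    hair_tophat_radius: int = 5
    hair_binarize_thresh: float = 20.0
    hair_use_otsu: bool = False
    hair_min_elongation: float = 4.0
    hair_min_length: float = 30.0
    hair_inpaint_radius: int = 5
    # segmentation
    grow_tolerance: float | None = None  # None -> 0.1 x intensity range
    grow_pre_smooth_sigma: float = 0.0
    # smoothing / detection
    smoothing_size: int = 15
    smoothing_sigma: float = 2.5
    min_prominence: float = 0.5
    count_minima: bool = False
    # evaluation
    match_tol_fraction: float = 0.02
    radial_samples: int = 360

    _RANGES = {
        "frame_lightness_thresh": (0.0, 255.0),
        "frame_black_row_fraction": (0.0, 1.0),
        "frame_extra_rows": (0, 100),
        "hair_tophat_radius": (1, 50),
        "hair_binarize_thresh": (0.0, 255.0),
        "hair_min_elongation": (1.0, 1000.0),
        "hair_min_length": (0.0, 10000.0),
        "hair_inpaint_radius": (1, 50),
        "grow_pre_smooth_sigma": (0.0, 50.0),
        "smoothing_size": (3, 999),
        "smoothing_sigma": (1e-6, 100.0),
        "min_prominence": (0.0, 255.0),
        "match_tol_fraction": (1e-6, 1.0),
        "radial_samples": (8, 100000),
    }

    def __post_init__(self) -> None:
        for name, (lo, hi) in self._RANGES.items():
            v = getattr(self, name)
            if not (lo <= v <= hi):
                raise ConfigError(f"{name}={v!r} outside [{lo}, {hi}]")
        if self.smoothing_size % 2 == 0:
            raise ConfigError("smoothing_size must be odd")
        if self.grow_tolerance is not None and self.grow_tolerance < 0:
            raise ConfigError("grow_tolerance must be >= 0 (or None for adaptive)")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def with_overrides(self, **overrides) -> "PipelineConfig":
        clean = {k: v for k, v in overrides.items() if v is not None}
        unknown = set(clean) - {f.name for f in dataclasses.fields(self)}
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return dataclasses.replace(self, **clean)

    @classmethod
    def from_toml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        return cls().with_overrides(**data).with_overrides(**overrides)
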