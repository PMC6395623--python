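"""Analysis configuration shared by the library, CLI and batch runner."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import yaml

from .errors import ParameterError


@dataclass
class AnalysisConfig:
    """Parameters of the directionality pipeline.

    Defaults follow the reference protocol: an 825 px centred crop (odd, so
    the recentred spectrum has a true central DC pixel), a 64 px corner block
    for the noise cutoff, 180 one-degree sectors, no window, DC excluded.
    """

    crop_px: int = 825
    corner_px: int = 64
    n_sectors: int = 180
    window: str = "none"  # none | hann
    exclude_dc: bool = True
    seed: int = 0  # for stochastic subcommands (phantom generation)

    def __post_init__(self):
        if self.crop_px < 3:
            raise ParameterError(f"crop_px must be >= 3, got {self.crop_px}")
        if self.crop_px % 2 == 0:
            warnings.warn(
                f"crop_px={self.crop_px} is even; the DC pixel sits at index "
                f"crop_px//2 and the Nyquist row/column is unpaired. An odd "
                f"crop is recommended.", stacklevel=2)
        if self.corner_px > (self.crop_px - 1) // 2 - 1:
            raise ParameterError(
                f"corner_px={self.corner_px} too large for crop_px="
                f"{self.crop_px}: corner blocks would overlap the centre")
        if self.window not in ("none", "hann"):
            raise ParameterError(f"window must be none|hann, got {self.window!r}")
        if self.n_sectors < 8:
            raise ParameterError(f"n_sectors must be >= 8, got {self.n_sectors}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_file(cls, path, **overrides) -> "AnalysisConfig":
        """Load a YAML/JSON config file; keyword overrides win over the file."""
        with open(Path(path)) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ParameterError(f"config file {path} must hold a mapping")
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)
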