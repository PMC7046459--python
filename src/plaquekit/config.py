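"""Run configuration shared by the CLI subcommands.

All physical constants of the quantification live here with their defaults:
34 µm² minimum object size for costained fluorescence channels, 9 µm² for
X-34, 17 µm constrained dilation, 80th/50th compact/diffuse percentiles and
the 99.99th-percentile control background threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

from .segmentation import ShapeLimits

__all__ = ["QuantConfig"]


@dataclass
class QuantConfig:
    pixel_size_um: float | None = None
    tophat_radius_um: float = 25.0
    local_window_um: float = 75.0
    local_offset: float = 0.0
    min_size_um2: float = 34.0        # costain channels
    min_size_x34_um2: float = 9.0     # X-34 channel
    dilation_radius_um: float = 17.0
    compact_percentile: float = 80.0
    diffuse_percentile: float = 50.0
    control_percentile: float = 99.99
    coloc_thresholds: dict = field(default_factory=dict)  # channel -> threshold
    shape_solidity_min: float = 0.5
    shape_roundness_min: float = 0.2
    aggregation: str = "pooled"       # section-level fraction aggregation
    log2_floor: float | None = None   # optional floor before gene-set scoring
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("compact_percentile", "diffuse_percentile", "control_percentile"):
            v = getattr(self, name)
            if not 0 < v < 100:
                raise ValueError(f"{name} must lie in (0, 100), got {v}")
        if self.compact_percentile <= self.diffuse_percentile:
            raise ValueError("compact_percentile must exceed diffuse_percentile")
        for name in ("tophat_radius_um", "local_window_um", "dilation_radius_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.aggregation not in ("pooled", "mean"):
            raise ValueError("aggregation must be 'pooled' or 'mean'")

    @property
    def shape_limits(self) -> ShapeLimits:
        return ShapeLimits(solidity=self.shape_solidity_min, roundness=self.shape_roundness_min)

    @classmethod
    def from_yaml(cls, path) -> "QuantConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)
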