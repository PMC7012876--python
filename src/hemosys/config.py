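"""Run configuration shared by all analysis modules.

The defaults encode the analysis parameters the toolkit was designed
around: a 30% oxygen-saturation threshold for hypoxia detection, 50x50
pixel sub-regions, a 5-minute mean filter advanced in 1-minute steps, a
Pearson correlation threshold of 0.7, a minimum cluster size of 5% of the
field of view, a -60 dB spectral noise floor, and low/high vasomotion
frequency bands covering 10-56 and 2-10 minute periods respectively.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml


@dataclass
class RunConfig:
    hypoxia_threshold_pct: float = 30.0
    block_px: int = 50
    temporal_kernel_min: float = 5.0
    temporal_step_min: float = 1.0
    cadence_min: float = 0.5
    corr_threshold: float = 0.7
    min_cluster_frac: float = 0.05
    noise_floor_db: float = -60.0
    lf_period_range_min: tuple[float, float] = (10.0, 56.0)
    hf_period_range_min: tuple[float, float] = (2.0, 10.0)

    def __post_init__(self) -> None:
        if not (0.0 < self.corr_threshold <= 1.0):
            raise ValueError("corr_threshold must lie in (0, 1]")
        if not (0.0 < self.min_cluster_frac < 1.0):
            raise ValueError("min_cluster_frac must lie in (0, 1)")
        if self.block_px < 1:
            raise ValueError("block_px must be a positive pixel count")
        for name in ("temporal_kernel_min", "temporal_step_min", "cadence_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0.0 <= self.hypoxia_threshold_pct <= 100.0):
            raise ValueError("hypoxia_threshold_pct must be a percentage")
        self.lf_period_range_min = tuple(self.lf_period_range_min)  # type: ignore[assignment]
        self.hf_period_range_min = tuple(self.hf_period_range_min)  # type: ignore[assignment]
        for lo, hi in (self.lf_period_range_min, self.hf_period_range_min):
            if lo <= 0 or hi < lo:
                raise ValueError("period ranges must be positive with upper >= lower")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        """Load a configuration from a YAML file mirroring the field names."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}  # noqa: C416
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["lf_period_range_min"] = list(self.lf_period_range_min)
        d["hf_period_range_min"] = list(self.hf_period_range_min)
        return d
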