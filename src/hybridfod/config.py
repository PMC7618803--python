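"""Pipeline configuration with the study's default constants."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import yaml

from .tracking import TrackingParams

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """All stage parameters in one place.

    Defaults reproduce the study constants: population exclusion below a
    signal fraction of 0.05, order-8 spherical harmonics on 256 sphere
    points, the tracking protocol (0.2 mm step, 0.05 cut-off, 5-120 mm,
    30 seeds/voxel), refinement thresholds (atlas probability 0.2, length
    4 SD, core deviation 5 SD), and the tracer-comparison thresholds
    (reference binarised at 1e-4, prediction thresholds on [0, 0.25],
    correlation floors 1e-4 / 1e-6).
    """

    seed: int = 0
    min_fraction: float = 0.05
    sh_order: int = 8
    n_sphere_points: int = 256
    fod_scale: str = "maxpeak"
    match_mode: str = "sampled"
    tracking: TrackingParams = field(default_factory=TrackingParams)
    atlas_probability_threshold: float = 0.2
    length_sd: float = 4.0
    deviation_sd: float = 5.0
    fixel_density_threshold: float = 0.05
    ref_threshold: float = 1e-4
    pred_threshold_max: float = 0.25
    n_pred_thresholds: int = 101
    pred_floor: float = 1e-4
    ref_floor: float = 1e-6

    def __post_init__(self):
        if isinstance(self.tracking, dict):
            self.tracking = TrackingParams(**self.tracking)
        if self.min_fraction < 0 or self.min_fraction >= 1:
            raise ValueError("min_fraction must lie in [0, 1)")
        if self.sh_order < 0 or self.sh_order % 2:
            raise ValueError("sh_order must be even and non-negative")
        if self.n_sphere_points % 2 or self.n_sphere_points < 16:
            raise ValueError("n_sphere_points must be an even count >= 16")
        if self.fod_scale not in ("maxpeak", "l0"):
            raise ValueError("fod_scale must be 'maxpeak' or 'l0'")
        if self.match_mode not in ("sampled", "argmax"):
            raise ValueError("match_mode must be 'sampled' or 'argmax'")
        if not (0 <= self.atlas_probability_threshold <= 1):
            raise ValueError("atlas_probability_threshold must lie in [0, 1]")

    @property
    def pred_thresholds(self) -> np.ndarray:
        return np.linspace(0.0, self.pred_threshold_max, self.n_pred_thresholds)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)
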