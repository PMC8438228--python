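"""Pipeline configuration: defaults < YAML file < CLI flags."""

from __future__ import annotations

from dataclasses import dataclass, fields, replace

import yaml

from .errors import DomainError
from . import rp_scoring

__all__ = ["PipelineConfig", "load_config"]


@dataclass(frozen=True)
class PipelineConfig:
    epsilon: float = rp_scoring.DEFAULT_EPSILON
    theta: float = rp_scoring.DEFAULT_THETA
    d0: float = rp_scoring.DEFAULT_D0
    normalization: str = "none"   # "none" or "cpm"
    round_dp: int = 2             # dichotomization threshold rounding
    horizon_days: float = 90.0    # cumulative-incidence horizon
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise DomainError("epsilon must be positive")
        if self.theta <= 0:
            raise DomainError("theta must be positive")
        if self.d0 <= 0:
            raise DomainError("d0 must be positive")
        if self.normalization not in ("none", "cpm"):
            raise DomainError(f"unknown normalization {self.normalization!r}")
        if self.round_dp < 0:
            raise DomainError("round_dp must be >= 0")
        if self.horizon_days <= 0:
            raise DomainError("horizon_days must be positive")


def load_config(path=None, **overrides) -> PipelineConfig:
    """Build a config from an optional YAML file plus keyword overrides.

    Unknown keys in the file are rejected; overrides with value ``None``
    (unset CLI flags) are ignored.
    """
    cfg = PipelineConfig()
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(PipelineConfig)}
        unknown = set(data) - known
        if unknown:
            raise DomainError(f"unknown config key(s): {sorted(unknown)}")
        cfg = replace(cfg, **data)
    effective = {k: v for k, v in overrides.items() if v is not None}
    if effective:
        cfg = replace(cfg, **effective)
    return cfg
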