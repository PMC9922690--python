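"""Pipeline configuration (YAML-backed)."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "load_config", "save_config"]

#: default Euclidean-norm censor limits per mode (mm)
MOTION_LIMITS = {"rest": 0.2, "task": 0.3}


@dataclass
class PipelineConfig:
    """Options for the one-command quick-QC driver."""

    mode: str = "rest"
    L_motion: float | None = None     # None = mode default (0.2 / 0.3)
    L_out: float = 0.05
    cost: str = "lpc"
    flip_margin_rel: float = 0.05
    radcor_fwhm_mm: float = 40.0
    seed_mm: str | None = None        # e.g. "5L, 49P, 40S"
    motion_derivatives: bool = True
    seed: int = 0
    report: bool = True

    def __post_init__(self) -> None:
        if self.mode not in MOTION_LIMITS:
            raise ValueError(f"mode must be 'rest' or 'task', got {self.mode!r}")
        if self.L_motion is None:
            self.L_motion = MOTION_LIMITS[self.mode]
        if self.L_motion <= 0 or self.L_out <= 0:
            raise ValueError("censor limits must be positive")


def load_config(path: str | Path) -> PipelineConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    return PipelineConfig(**data)


def save_config(config: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(asdict(config), sort_keys=False))
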