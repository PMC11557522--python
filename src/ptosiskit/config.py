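"""Run configuration: a single validated schema shared by every CLI stage.

Unknown keys are rejected so typos fail loudly before any stage runs. All
coordinates in files produced under a config are 0-based, y-down, subpixel
floats; all randomness flows from the single ``seed``.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, model_validator

from .errors import ConfigurationError

__all__ = ["RunConfig", "load_config"]


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    # backend
    backend: Literal["geometric_warp", "ddpm_toy", "controlnet"] = "geometric_warp"
    strength: float = 1.0

    # target specification
    target_source: Literal["fellow_eye", "explicit"] = "fellow_eye"
    target_mrr: Optional[float] = None
    crease_offset: float = 0.0

    # conditioning artifacts
    canny_low: float = 50.0
    canny_high: float = 150.0
    mask_margin: float = 5.0
    edges_off: bool = False
    mask_off: bool = False

    # evaluation
    angle_step: float = 15.0
    supersample: int = 4

    # synthetic cohort
    n: int = 26
    severity_low: float = 0.05
    severity_high: float = 0.55

    # randomness
    seed: int = 0

    @model_validator(mode="after")
    def _ranges(self) -> "RunConfig":
        if self.canny_low >= self.canny_high:
            raise ValueError("canny_low must be < canny_high")
        if self.target_source == "explicit" and self.target_mrr is None:
            raise ValueError("explicit target_source requires target_mrr")
        if self.target_mrr is not None and not (0.0 < self.target_mrr <= 1.2):
            raise ValueError("target_mrr must lie in (0, 1.2]")
        if self.severity_low > self.severity_high:
            raise ValueError("empty severity range")
        if not (0.0 <= self.strength <= 1.0):
            raise ValueError("strength must lie in [0, 1]")
        return self


def load_config(path: str | Path | None, **overrides) -> RunConfig:
    """Load YAML config (or defaults when ``path`` is None) with overrides."""
    data: dict = {}
    if path is not None:
        p = Path(path)
        if not p.exists():
            raise ConfigurationError(f"config file not found: {p}")
        loaded = yaml.safe_load(p.read_text())
        if loaded is not None:
            if not isinstance(loaded, dict):
                raise ConfigurationError(f"config root must be a mapping: {p}")
            data = loaded
    data.update({k: v for k, v in overrides.items() if v is not None})
    try:
        return RunConfig(**data)
    except Exception as exc:  # pydantic ValidationError and friends
        raise ConfigurationError(str(exc)) from exc
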