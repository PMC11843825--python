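"""Run configuration: a validated schema for the end-to-end pipeline.

Unknown keys are rejected so typos fail loudly. The defaults describe a
small simulated run that exercises every stage in about a minute.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

__all__ = ["RunConfig", "ConfigError", "load_config"]


class ConfigError(ValueError):
    """Invalid or unreadable run configuration."""


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimulateSettings(_Strict):
    n_wounds: int = 6
    segments_per_wound_mean: float = 4.6
    wound_box_px: int = 12
    pixel_pitch_mm: float = 0.5
    spectral_noise_sd: float = 0.005
    spread_scale: float = 1.0
    balanced_classes: bool = True
    enabled: bool = True  # off: read an existing cohort from input_dir
    input_dir: str | None = None


class ModelSettings(_Strict):
    xa: float = Field(0.98, gt=0, le=1)


class InverseSettings(_Strict):
    n_starts: int = 2
    smoothness: float = 0.05
    polish_smoothness: float = 0.007
    max_nfev: int = 100


class SegmentationSettings(_Strict):
    tau: float = 0.07
    min_area: int = 4
    single_class_tolerance: float = 0.95
    # channels entering the homogeneity criterion; the composed-volume
    # channels and xrate are per-pixel robust, while the saturation/flow
    # channels carry amplified inversion noise
    channels: tuple[str, ...] = ("v1", "v2", "v3", "xrate")


class KdeSettings(_Strict):
    grid_n: int = 200
    mass: float = Field(0.68, gt=0, lt=1)
    bandwidth: float | None = None


class ClassificationSettings(_Strict):
    leave_one_wound_out: bool = False


class IoSettings(_Strict):
    cube_dialect: str = "envi"

    @field_validator("cube_dialect")
    @classmethod
    def _dialect(cls, v):
        if v not in ("envi", "npz"):
            raise ValueError("cube_dialect must be 'envi' or 'npz'")
        return v


class RunConfig(_Strict):
    seed: int = 0
    simulate: SimulateSettings = SimulateSettings()
    model: ModelSettings = ModelSettings()
    inverse: InverseSettings = InverseSettings()
    segmentation: SegmentationSettings = SegmentationSettings()
    kde: KdeSettings = KdeSettings()
    classification: ClassificationSettings = ClassificationSettings()
    io: IoSettings = IoSettings()


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    try:
        raw = yaml.safe_load(path.read_text()) or {}
        return RunConfig(**raw)
    except Exception as exc:
        raise ConfigError(f"invalid config {path}: {exc}") from exc
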