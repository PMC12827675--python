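"""Declarative run configuration with schema validation.

Unknown keys are rejected (no silent ignoring); defaults are filled in and
echoed back so a run manifest always records the full effective configuration.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PceSettings(_Strict):
    enabled: Literal["off", "pce", "histeq"] = "pce"
    delta_h: int = 30
    alpha: float = Field(0.8, ge=0)
    beta: float = Field(15.0, ge=0)
    colorize_mode: Literal["replicate", "intensity_to_hue"] = "intensity_to_hue"


class ModelSettings(_Strict):
    shallow: str = "tinycnn-shallow"
    deep: str = "tinycnn-deep"
    proj_dim: int = Field(256, gt=0)
    variant: Literal["concat_raw", "concat_projected"] = "concat_raw"
    pool_size: int = Field(1, gt=0)
    pretrained: str | None = None


class LossSettings(_Strict):
    lam: float = Field(0.3, ge=0, alias="lambda")
    sim_reduction: Literal["mean", "sum"] = "mean"
    model_config = ConfigDict(extra="forbid", populate_by_name=True)


class WindowSettings(_Strict):
    total_slices: int = Field(10, ge=1)
    m: int = Field(1, ge=0)

    @model_validator(mode="after")
    def _check_m(self):
        if 2 * self.m + 1 > self.total_slices:
            raise ValueError("2m+1 slices must fit inside the Z-window")
        return self


class TrainSettings(_Strict):
    epochs: int = Field(150, ge=1)
    learning_rate: float = Field(3e-4, gt=0)
    optimizer: Literal["adam", "sgd"] = "adam"
    batch_size: int = Field(32, ge=1)
    augment: bool = False
    test_fraction: float = Field(0.3, gt=0, lt=1)


class PhantomSettings(_Strict):
    n_patients: int = Field(100, ge=2)
    n_slices: int = Field(64, ge=1)
    height: int = Field(256, ge=32)
    width: int = Field(256, ge=32)
    spacing_xy: float = Field(0.4, gt=0)
    spacing_z: float = Field(1.0, gt=0)


class RunConfig(_Strict):
    seed: int = 0
    vote: Literal["majority", "average"] = "majority"
    eval_mode: Literal["split", "cv"] = "split"
    cv_folds: int = Field(5, ge=2)
    pce: PceSettings = PceSettings()
    model: ModelSettings = ModelSettings()
    loss: LossSettings = LossSettings()
    window: WindowSettings = WindowSettings()
    train: TrainSettings = TrainSettings()
    phantom: PhantomSettings = PhantomSettings()


def validate_config(data: dict | None = None) -> RunConfig:
    """Validate a (possibly partial) config mapping; defaults are filled and
    the complete configuration returned.  Unknown keys raise."""
    return RunConfig.model_validate(data or {})


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        return validate_config(yaml.safe_load(fh) or {})


def dump_config(config: RunConfig) -> dict:
    return config.model_dump(by_alias=True)
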