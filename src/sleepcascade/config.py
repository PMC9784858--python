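"""Validated pipeline configuration (YAML-backed, unknown keys rejected)."""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field


class PipelineConfig(BaseModel):
    """All tunables of a pipeline run, validated before any computation."""

    model_config = ConfigDict(extra="forbid")

    # wavelet preprocessing
    wtd_wavelet: str = "db8"
    wtd_levels: int = Field(7, ge=1)
    threshold_rule: str = "universal"
    wpt_wavelet: str = "db20"
    wpt_levels: int = Field(7, ge=1)
    extension_mode: str = "symmetric"
    bands: dict[str, tuple[float, float]] | None = None

    # features
    mse_tau: int = Field(11, ge=1)

    # selection
    n_bins: int = Field(10, ge=2)
    top_stage1: int = Field(32, ge=1)
    top_stage2: int = Field(30, ge=1)

    # classifier
    const: float = Field(1.0, gt=0)
    const_grid: list[float] | None = None
    cv_folds: int = Field(10, ge=2)

    # evaluation
    n_repeats: int = Field(5, ge=1)
    test_fraction: float = Field(0.1, gt=0, lt=1)
    stratify: bool = True

    # synthetic data
    n_epochs_per_stage: int = Field(200, ge=1)
    separation: float = Field(1.0, gt=0)

    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls(**payload)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(), fh, sort_keys=True)
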