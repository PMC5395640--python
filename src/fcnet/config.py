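"""Validated run configuration.

A :class:`RunConfig` collects every knob the pipeline exposes.  Defaults are
the analysis' canonical values: discard 10 volumes, 0.01-0.1 Hz band,
FD threshold 0.3 mm at 50 mm radius, 2 mm / 2 degree gross-motion limits,
sparsity grid 0.11-0.30 in steps of 0.01, 100 nulls, 5000 permutations.
Validation happens up front (pydantic), before any stage runs.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, Field, model_validator

from .model import DEFAULT_COVARIATES


class PreprocessConfig(BaseModel):
    k_discard: int = Field(10, ge=0)
    band_low_hz: float = Field(0.01, gt=0)
    band_high_hz: float = Field(0.1, gt=0)
    fd_threshold_mm: float = Field(0.3, gt=0)
    fd_radius_mm: float = Field(50.0, gt=0)
    translation_limit_mm: float = Field(2.0, gt=0)
    rotation_limit_deg: float = Field(2.0, gt=0)
    min_kept_fraction: float = Field(0.5, ge=0, le=1)
    filter_method: str = "butter"

    @model_validator(mode="after")
    def _band_order(self) -> "PreprocessConfig":
        if self.band_low_hz >= self.band_high_hz:
            raise ValueError("band_low_hz must be below band_high_hz")
        return self


class GridConfig(BaseModel):
    t_min: float = Field(0.11, gt=0, lt=1)
    t_max: float = Field(0.30, gt=0, lt=1)
    step: float = Field(0.01, gt=0)

    @model_validator(mode="after")
    def _ordered(self) -> "GridConfig":
        if self.t_min > self.t_max:
            raise ValueError("t_min must not exceed t_max")
        return self


class RunConfig(BaseModel):
    """Full pipeline configuration (YAML-serialisable)."""

    input_dir: str | None = None
    output_dir: str = "fcnet_out"
    preprocess: PreprocessConfig = Field(default_factory=PreprocessConfig)
    grid: GridConfig = Field(default_factory=GridConfig)
    n_random_nulls: int = Field(100, ge=1)
    n_permutations: int = Field(5000, ge=100)
    covariates: list[str] = Field(default_factory=lambda:
                                  list(DEFAULT_COVARIATES))
    compute_betweenness: bool = True
    seed: int | None = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.model_validate(raw)

    def to_yaml(self, path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.model_dump(), sort_keys=False)
        )

    def preprocess_options(self) -> dict:
        p = self.preprocess
        return {
            "k_discard": p.k_discard,
            "band": (p.band_low_hz, p.band_high_hz),
            "fd_threshold": p.fd_threshold_mm,
            "fd_radius": p.fd_radius_mm,
            "translation_limit_mm": p.translation_limit_mm,
            "rotation_limit_deg": p.rotation_limit_deg,
            "min_kept_fraction": p.min_kept_fraction,
            "filter_method": p.filter_method,
        }

    def sparsity_grid(self):
        from .netcon import sparsity_grid

        return sparsity_grid(self.grid.t_min, self.grid.t_max, self.grid.step)
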