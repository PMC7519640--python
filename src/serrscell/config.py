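"""Validated run configuration (YAML-loadable, unknown keys rejected)."""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GridConfig(_Section):
    start_cm1: float = 400.0
    stop_cm1: float = 1800.0
    n_points: int = 1024


class NoiseConfig(_Section):
    baseline_coeffs: tuple[float, ...] = (0.05, 0.05)
    additive_sd: float = Field(default=0.20, ge=0)
    shot_noise: bool = False
    fluorescence_amplitude: float = Field(default=0.05, ge=0)


class ExperimentConfig(_Section):
    lncap_per_ml: float = 24.0
    u251_per_ml: float = 29.0
    pbmc_per_ml: float = 1.0e7
    depletion: float = Field(default=0.9999, ge=0, le=1)
    efficiency: float = Field(default=0.84, gt=0, le=1)
    volume_ml: float = Field(default=1.0, gt=0)
    chamber_mm: float = Field(default=3.5, gt=0)
    pixel_size_um: float = Field(default=1.0, gt=0)
    pbmc_scale: float = Field(default=1.0, gt=0, le=1)


class GateConfig(_Section):
    lower_um2: float = 30.0
    upper_um2: float = 180.0
    min_pixels: int = Field(default=4, ge=1)
    connectivity: int = 8


class ScoringConfig(_Section):
    preprocess: str = "none"  # "none" | "linear"
    tau_pos: float = Field(default=0.5, gt=-1, lt=1)


class ForestSection(_Section):
    n_trees: int = Field(default=5000, ge=1)
    m_try: int = Field(default=3, ge=1)
    interaction_features: bool = False


class PoolsConfig(_Section):
    """Sizes of the single-phenotype reference samples (pre-gate)."""

    n_lncap: int = 300
    n_u251: int = 300
    n_pbmc: int = 3000


class CalibrationConfig(_Section):
    grid_start_pct: float = 35.0
    grid_stop_pct: float = 95.0
    grid_step_pct: float = 5.0
    tolerance: int = Field(default=2, ge=0)
    n_mixes: int = Field(default=5, ge=1)
    #: Fixed attribution threshold; when null the threshold is calibrated.
    tau_attr_pct: float | None = None


class RunConfig(_Section):
    seed: int = 0
    grid: GridConfig = GridConfig()
    noise: NoiseConfig = NoiseConfig()
    experiment: ExperimentConfig = ExperimentConfig()
    gate: GateConfig = GateConfig()
    scoring: ScoringConfig = ScoringConfig()
    forest: ForestSection = ForestSection()
    pools: PoolsConfig = PoolsConfig()
    calibration: CalibrationConfig = CalibrationConfig()
    n_bootstrap: int = Field(default=1000, ge=2)


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(raw)
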