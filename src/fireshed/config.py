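"""Campaign configuration: schema-validated YAML with documented defaults.

Thresholds default to the analysis constants: probability threshold 0.3,
slope limit 30%, composition minimum 0.65, burn return intervals 10/15 yr,
thin fraction 0.30, layer-difference exceedance threshold 20 Mg C/ha, and
t-test significance level 0.01.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator


class ConfigError(ValueError):
    pass


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class LandscapeSection(_Section):
    n_rows: int = Field(100, ge=1)
    n_cols: int = Field(100, ge=1)
    cell_size: float = Field(100.0, gt=0)
    elevation_min: float = 1900.0
    elevation_max: float = 3700.0
    n_soils: int = Field(6, ge=1)
    n_spectral: int = Field(3, ge=1)
    aspen_fraction: float = Field(0.03, ge=0, le=0.25)
    nonforest_fraction: float = Field(0.12, ge=0, lt=1)
    shrub_fraction: float = Field(0.08, ge=0, lt=1)
    measurement_noise_sigma: float = Field(0.1, ge=0)

    @model_validator(mode="after")
    def _check_elevation(self):
        if self.elevation_max <= self.elevation_min:
            raise ValueError("elevation_max must exceed elevation_min")
        return self


class PlotsSection(_Section):
    n_fia: int = Field(68, ge=1)
    n_stands: int = Field(111, ge=1)
    plots_per_stand_min: int = Field(3, ge=3, le=31)
    plots_per_stand_max: int = Field(31, ge=3, le=31)

    @model_validator(mode="after")
    def _check_range(self):
        if self.plots_per_stand_max < self.plots_per_stand_min:
            raise ValueError("plots_per_stand_max below plots_per_stand_min")
        return self


class ImputationSection(_Section):
    select_covariates: bool = False


class SimulatorSection(_Section):
    growth_rate: float = Field(0.12, gt=0)
    mortality_fraction: float = Field(0.008, ge=0, lt=1)
    ignition_rate: float = Field(1.2, ge=0)
    fire_size_median_cells: float = Field(40.0, gt=0)
    fire_size_sigma: float = Field(0.9, gt=0)
    high_severity_kill: float = Field(0.8, ge=0.5, le=1.0)
    thin_fraction: float = Field(0.30, gt=0, lt=1)


class ZoningSection(_Section):
    prob_threshold: float = Field(0.3, ge=0, le=1)
    slope_max_percent: float = Field(30.0, ge=0)
    composition_min: float = Field(0.65, ge=0, le=1)
    codominance_threshold: float = Field(0.2, ge=0, le=1)
    burn_interval_short: int = Field(10, ge=1)
    burn_interval_long: int = Field(15, ge=1)


class ExperimentSection(_Section):
    levels: list[int] = Field(default_factory=lambda: [536, 268, 134, 67])
    replicates: int = Field(25, ge=1)
    n_climates: int = Field(5, ge=1, le=5)
    years: int = Field(50, ge=1)
    exceedance_threshold: float = Field(20.0, gt=0)  # Mg C/ha
    alpha: float = Field(0.01, gt=0, lt=1)
    ttest_interval_years: int = Field(10, ge=1)


class CampaignConfig(_Section):
    landscape: LandscapeSection = LandscapeSection()
    plots: PlotsSection = PlotsSection()
    imputation: ImputationSection = ImputationSection()
    simulator: SimulatorSection = SimulatorSection()
    zoning: ZoningSection = ZoningSection()
    experiment: ExperimentSection = ExperimentSection()
    output_dir: str = "results"


def validate_config(path: str | Path | None = None,
                    data: dict | None = None) -> CampaignConfig:
    """Load and validate a campaign YAML; an empty file yields pure defaults.

    Unknown keys and out-of-range thresholds are rejected, with all
    violations listed in the error.
    """
    if data is None:
        if path is None:
            data = {}
        else:
            with open(path) as fh:
                data = yaml.safe_load(fh) or {}
    try:
        return CampaignConfig.model_validate(data)
    except ValidationError as err:
        msgs = "; ".join(f"{'.'.join(str(p) for p in e['loc'])}: {e['msg']}"
                         for e in err.errors())
        raise ConfigError(f"invalid campaign config: {msgs}") from err
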