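"""Run configuration: schema-validated YAML with case-study defaults."""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator


class MillBlock(BaseModel):
    """Wet-mill inputs (defaults: the bundled case study)."""

    model_config = ConfigDict(extra="forbid")

    water_quantity_mL: float = 9.0
    api_content_g: float = 0.5
    stabilizer_content_g: float = 0.25
    mannitol_content_g: float = 1.0
    initial_d50_um: float = 1.5
    initial_gsd: float = 1.5  # geometric SD of the feed PSD
    grinding_time_h: float = 1.0
    rotor_speed_rpm: float = 600.0
    rotor_diameter_mm: float = 40.0
    mill_volume_mL: float = 48.0
    grid_x_max_um: float = 5.0
    grid_x_min_um: float = 0.05
    grid_n_bins: int = 20

    @field_validator(
        "water_quantity_mL",
        "api_content_g",
        "initial_d50_um",
        "grinding_time_h",
        "mill_volume_mL",
        "grid_x_max_um",
        "grid_x_min_um",
    )
    @classmethod
    def _positive(cls, value):
        if value <= 0:
            raise ValueError("must be positive")
        return value


class DryerBlock(BaseModel):
    """Spray-dryer inputs mirroring the operating table."""

    model_config = ConfigDict(extra="forbid")

    air_temperature_C: float = 110.0
    air_flow_L_h: float = 800.0
    air_pressure_bar: float = 5.0
    chamber_volume_L: float = 5.0
    drying_time_h: float = 1.0
    residence_time_s: float = 22.5
    inlet_humidity: float = 0.005
    heat_transfer_coeff: float = 1000.0
    critical_moisture: float = 1.0
    droplet_median_um: float = 20.0
    droplet_gsd: float = 1.8
    n_droplet_bins: int = 5
    n_solids_bins: int = 4
    n_steps: int = 400
    bdf_order: int = 2


class SurrogateBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")

    hidden_layers: list[int] = Field(default=[8, 8])
    epochs: int = 20000
    learning_rate: float = 0.05
    polynomial_order: int = 2
    n_dense: int = 61  # points of the dense reference profile


class FitBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")

    families: list[str] = Field(default=["austin", "kapur", "de_vegt"])
    n_starts: int = 8
    max_nfev: int = 60
    b_exponent: float = 1.25


class StageToggles(BaseModel):
    model_config = ConfigDict(extra="forbid")

    stabilizer: bool = True
    augment: bool = True
    milling: bool = True
    spraydry: bool = True


class RunConfig(BaseModel):
    """Digital-twin thread configuration (all units explicit in field names)."""

    model_config = ConfigDict(extra="forbid")

    materials_file: Optional[str] = None
    output_dir: str = "twin_output"
    seed: int = 2022
    mill: MillBlock = Field(default_factory=MillBlock)
    dryer: DryerBlock = Field(default_factory=DryerBlock)
    surrogate: SurrogateBlock = Field(default_factory=SurrogateBlock)
    fit: FitBlock = Field(default_factory=FitBlock)
    stages: StageToggles = Field(default_factory=StageToggles)


def load_config(path=None, overrides: Optional[dict] = None) -> RunConfig:
    """Load and validate a YAML run configuration.

    Missing keys take the case-study defaults; unknown keys raise a
    validation error naming the offending entries.  ``path=None`` yields
    the all-defaults configuration.
    """
    data = {}
    if path is not None:
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(path)
        data = yaml.safe_load(path.read_text()) or {}
    if overrides:
        data.update(overrides)
    return RunConfig.model_validate(data)


def dump_config(config: RunConfig, path=None) -> str:
    """Serialize a configuration back to YAML (round-trips with load)."""
    text = yaml.safe_dump(config.model_dump(), sort_keys=False)
    if path is not None:
        Path(path).write_text(text)
    return text
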