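"""Run configuration: schema, units, YAML I/O and hashing.

A :class:`ModelConfig` bundles everything a simulation needs — parameters,
forcings, tourist profile, initial stocks, numerical settings, optional
per-flux calibration multipliers, optional extra pass-through emission
terms and optional added sink projects.  Configs are immutable; scenario
transforms return modified copies.

The on-disk format is YAML with one section per component.  Unknown keys
are rejected.  An optional ``units`` section may restate the unit of any
field; a restated unit must match the canonical unit table exactly —
units are validated, never guessed.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any, Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .model import (
    CONSTANTS,
    CarbonPools,
    Forcings,
    IslandParameters,
    ModelConstants,
    TouristProfile,
    FLUX_NAMES,
)

__all__ = [
    "ModelConfig",
    "SinkSpec",
    "ConfigError",
    "CANONICAL_UNITS",
    "load_config",
    "dump_config",
    "config_to_dict",
    "config_from_dict",
    "config_hash",
]


class ConfigError(ValueError):
    """A configuration file violated the schema; message carries the field path."""


class SinkSpec(BaseModel):
    """An added carbon-sink project (e.g. macroalgae farming): a constant
    areal removal rate over a managed area."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    name: str
    area_km2: float = Field(ge=0.0)
    rate_tc_per_km2: float = Field(ge=0.0, description="tC yr-1 km-2")

    @property
    def annual_tc(self) -> float:
        return self.area_km2 * self.rate_tc_per_km2


class ModelConfig(BaseModel):
    """Immutable, fully validated description of one simulation run."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    name: str = "unnamed"
    parameters: IslandParameters
    forcings: Forcings
    profile: TouristProfile
    initial_stocks: CarbonPools = CarbonPools()
    constants: ModelConstants = CONSTANTS
    dt: float = Field(default=1.0 / 12.0, gt=0.0, description="step, years")
    horizon: float = Field(default=1.0, gt=0.0, description="run length, years")
    temp_mode: Literal["clamp", "strict"] = "clamp"
    negative_stock: Literal["floor", "error"] = "floor"
    #: per-flux output multipliers (calibration knobs); default identity
    flux_multipliers: dict[str, float] = Field(default_factory=dict)
    #: named constant emission terms in tC/yr entering the CO2 stock from
    #: outside (food imports, residential electricity, ...); default none
    extra_emissions: dict[str, float] = Field(default_factory=dict)
    added_sinks: tuple[SinkSpec, ...] = ()
    #: free-form provenance notes (e.g. calibration derivations)
    provenance: dict[str, str] = Field(default_factory=dict)

    def model_post_init(self, __context: Any) -> None:
        unknown = set(self.flux_multipliers) - set(FLUX_NAMES)
        if unknown:
            raise ValueError(
                f"flux_multipliers reference unknown fluxes: {sorted(unknown)}"
            )
        for k, v in self.flux_multipliers.items():
            if v < 0:
                raise ValueError(f"flux multiplier {k!r} is negative: {v}")
        for k, v in self.extra_emissions.items():
            if v < 0:
                raise ValueError(f"extra emission {k!r} is negative: {v}")

    def with_updates(self, **sections: Any) -> "ModelConfig":
        """Return a copy with whole sections replaced (pure update)."""
        data = self.model_dump()
        data.update(sections)
        return ModelConfig.model_validate(data)

    def with_parameter_overrides(self, **overrides: float) -> "ModelConfig":
        params = self.parameters.model_copy(update=overrides)
        # model_copy skips validation; round-trip to validate
        params = IslandParameters.model_validate(params.model_dump())
        return self.with_updates(parameters=params.model_dump())


# canonical units of every scalar config field, keyed "section.field"
CANONICAL_UNITS: dict[str, str] = {
    "forcings.temp": "degC",
    "forcings.rade": "MJ m-2 yr-1",
    "forcings.nv": "visitors yr-1",
    "forcings.ni": "persons",
    "forcings.land_area": "km2",
    "forcings.inshore_area": "km2",
    "profile.sd": "fraction",
    "profile.hotel_r": "fraction",
    "profile.ph_r": "fraction",
    "profile.moto_r": "fraction",
    "profile.pc_r": "fraction",
    "profile.ssd_r": "fraction",
    "profile.pd_moto": "km day-1",
    "profile.pd_pc": "km day-1",
    "profile.pd_ssd": "km day-1",
    "parameters.w_growth_r": "km-2 yr-1 (x light/temp factors)",
    "parameters.f_growth_r": "km-2 yr-1 (x light/temp factors)",
    "parameters.w_re_r": "km-2 yr-1 K-1",
    "parameters.f_re_r": "km-2 yr-1 K-1",
    "parameters.dec_r": "yr-1 K-1",
    "parameters.ads_r": "yr-1 K-1",
    "parameters.forest_frac": "fraction of land area",
    "parameters.tidal_frac": "fraction of land area",
    "parameters.aqu_frac": "fraction of inshore area",
    "parameters.growth_r": "mg C m-2 yr-1",
    "parameters.shell_c_r": "fraction",
    "parameters.ce_aqu": "g CO2 km-2 yr-1",
    "parameters.ce_car": "g CO2 car-1 yr-1",
    "parameters.ce_desalination": "g CO2 t-1",
    "parameters.ce_ferry": "g CO2 km-1",
    "parameters.ce_fishing": "g CO2 person-day-1",
    "parameters.ce_hotel": "g CO2 night-1",
    "parameters.ce_moto": "g CO2 km-1",
    "parameters.ce_pc": "g CO2 km-1",
    "parameters.ce_ph": "g CO2 night-1",
    "parameters.ce_shopping": "g CO2 person-day-1",
    "parameters.ce_ssb": "g CO2 km-1",
    "parameters.ce_visiting": "g CO2 person-day-1",
    "parameters.ce_wa": "g CO2 person-day-1",
    "parameters.dis_ferry": "km visitor-1",
    "parameters.per_wc": "t person-1 day-1",
    "parameters.per_waste": "kg person-1 day-1",
    "parameters.pch4_waste": "g CH4 kg-1",
    "parameters.ch4_use_r": "fraction",
    "parameters.car_r": "fraction",
    "initial_stocks.co2_exchange": "tC",
    "initial_stocks.forest_c": "tC",
    "initial_stocks.wetland_c": "tC",
    "initial_stocks.shell_c": "tC",
    "initial_stocks.soil_c": "tC",
    "initial_stocks.waste_ch4": "tC",
    "initial_stocks.total_ch4": "tC",
    "dt": "yr",
    "horizon": "yr",
    "flux_multipliers": "dimensionless",
    "extra_emissions": "tC yr-1",
}


def config_to_dict(config: ModelConfig) -> dict[str, Any]:
    """Plain-dict form (YAML/JSON friendly) of a config."""
    d = config.model_dump(mode="json")
    return d


def config_from_dict(data: dict[str, Any]) -> ModelConfig:
    """Validate a plain dict into a :class:`ModelConfig`.

    An optional ``units`` mapping is checked against the canonical table
    and then stripped.
    """
    if not isinstance(data, dict):
        raise ConfigError(f"config root must be a mapping, got {type(data).__name__}")
    data = dict(data)
    units = data.pop("units", None)
    if units is not None:
        if not isinstance(units, dict):
            raise ConfigError("units: must be a mapping of field path -> unit string")
        for path, unit in units.items():
            canonical = CANONICAL_UNITS.get(path)
            if canonical is None:
                raise ConfigError(f"units: unknown field path {path!r}")
            if unit != canonical:
                raise ConfigError(
                    f"units: field {path!r} declared as {unit!r} but the "
                    f"canonical unit is {canonical!r}"
                )
    try:
        return ModelConfig.model_validate(data)
    except ValidationError as exc:
        paths = "; ".join(
            ".".join(str(p) for p in err["loc"]) + ": " + err["msg"]
            for err in exc.errors()
        )
        raise ConfigError(f"invalid configuration: {paths}") from exc


def load_config(path: str | Path) -> ModelConfig:
    """Load and validate a YAML config file."""
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    return config_from_dict(raw)


def dump_config(config: ModelConfig, path: str | Path | None = None) -> str:
    """Serialize a config to YAML (and optionally write it)."""
    text = yaml.safe_dump(config_to_dict(config), sort_keys=True)
    if path is not None:
        Path(path).write_text(text)
    return text


def config_hash(config: ModelConfig) -> str:
    """Stable SHA-256 of the canonical JSON serialization (for run logs)."""
    payload = json.dumps(config_to_dict(config), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()
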