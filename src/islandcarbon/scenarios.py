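"""Policy-scenario engine: transform a config, re-run, compare budgets.

Scenarios are pure transforms on a :class:`~islandcarbon.config.ModelConfig`
(the base config is never mutated):

* ``electrify_island_transport`` — zero-carbon electricity replaces fossil
  fuel in all on-island road transport (resident cars, tourist cars, small
  shuttle buses, rental motorcycles);
* ``electrify_ferry`` — an electric ferry replaces the diesel ferry link
  to the mainland;
* ``add_macroalgae_sink`` — a macroalgae farming project beyond the mussel
  culture area adds a blue-carbon sink at a fixed areal rate
  (default 3350 tC/yr per km2).

``compare`` reports per-row and total deltas between a base and a scenario
budget, the percentage reduction of total emission, and the change in the
carbon credit.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from .budget import BudgetTable
from .config import ModelConfig, SinkSpec

__all__ = [
    "Scenario",
    "MACROALGAE_RATE_TC_PER_KM2",
    "electrify_island_transport",
    "electrify_ferry",
    "add_macroalgae_sink",
    "apply_scenario",
    "compare",
    "ComparisonReport",
    "SCENARIOS",
]

#: areal carbon-capture rate of farmed macroalgae, tC yr-1 km-2
MACROALGAE_RATE_TC_PER_KM2 = 3350.0

_ISLAND_TRANSPORT_COEFFS = ("ce_car", "ce_pc", "ce_ssb", "ce_moto")


class Scenario(BaseModel):
    """A declarative scenario: parameter overrides plus added sinks."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    name: str
    parameter_overrides: dict[str, float] = Field(default_factory=dict)
    added_sinks: tuple[SinkSpec, ...] = ()


def apply_scenario(config: ModelConfig, scenario: Scenario) -> ModelConfig:
    """Apply a declarative scenario; returns a new config."""
    out = config
    if scenario.parameter_overrides:
        out = out.with_parameter_overrides(**scenario.parameter_overrides)
    if scenario.added_sinks:
        out = out.with_updates(
            added_sinks=[s.model_dump() for s in (*out.added_sinks,
                                                  *scenario.added_sinks)]
        )
    return out.with_updates(name=f"{config.name}+{scenario.name}")


def electrify_island_transport(config: ModelConfig) -> ModelConfig:
    """Zero the emission coefficients of all on-island road transport."""
    return apply_scenario(
        config,
        Scenario(
            name="electrify_island_transport",
            parameter_overrides={c: 0.0 for c in _ISLAND_TRANSPORT_COEFFS},
        ),
    )


def electrify_ferry(config: ModelConfig) -> ModelConfig:
    """Zero the ferry emission coefficient; everything else untouched."""
    return apply_scenario(
        config, Scenario(name="electrify_ferry",
                         parameter_overrides={"ce_ferry": 0.0})
    )


def add_macroalgae_sink(
    config: ModelConfig,
    area_multiple: float,
    rate_tc_per_km2: float = MACROALGAE_RATE_TC_PER_KM2,
) -> ModelConfig:
    """Add a macroalgae sink sized as a multiple of the mussel-culture area."""
    if area_multiple < 0:
        raise ValueError(f"area_multiple={area_multiple} must be non-negative")
    area = area_multiple * config.parameters.aqu_frac * config.forcings.inshore_area
    return apply_scenario(
        config,
        Scenario(
            name="macroalgae_sink",
            added_sinks=(
                SinkSpec(name="macroalgae", area_km2=area,
                         rate_tc_per_km2=rate_tc_per_km2),
            ),
        ),
    )


SCENARIOS = {
    "electrify_island_transport": electrify_island_transport,
    "electrify_ferry": electrify_ferry,
    "add_macroalgae_sink": add_macroalgae_sink,
}


@dataclass(frozen=True)
class ComparisonReport:
    """Savings of a scenario run relative to a base run.

    ``row_deltas`` are base minus scenario (positive = the scenario saves
    carbon on that row).  ``emission_reduction_percent`` uses the base
    table's emission total — or its headline override when set — as the
    denominator.
    """

    row_deltas: dict[str, float]
    emission_saving: float
    sink_gain: float
    emission_reduction_percent: float
    credit_change: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.row_deltas.items()),
            columns=["row", "saving_tC_per_yr"],
        )

    def to_dict(self) -> dict:
        return {
            "row_deltas": self.row_deltas,
            "emission_saving": self.emission_saving,
            "sink_gain": self.sink_gain,
            "emission_reduction_percent": self.emission_reduction_percent,
            "credit_change": self.credit_change,
        }


def compare(base: BudgetTable, scenario: BudgetTable) -> ComparisonReport:
    """Element-wise savings report; the two tables must share row sets.

    Rows present only in the scenario (added sink projects) are allowed
    and enter the sink gain with a zero base value.
    """
    base_rows = {r.name: r for r in base.rows}
    scen_rows = {r.name: r for r in scenario.rows}
    missing = set(base_rows) - set(scen_rows)
    if missing:
        raise ValueError(f"scenario budget lacks rows present in base: {sorted(missing)}")
    deltas: dict[str, float] = {}
    for name, b in base_rows.items():
        s = scen_rows[name]
        if s.column != b.column:
            raise ValueError(f"row {name!r} changed column between tables")
        deltas[name] = b.value - s.value
    for name, s in scen_rows.items():
        if name not in base_rows:
            deltas[name] = -s.value  # new sink row: negative "saving", a gain below
    emission_saving = base.total_emission - scenario.total_emission
    sink_gain = scenario.total_sink - base.total_sink
    denom = (
        base.headline_emission
        if base.headline_emission is not None
        else base.total_emission
    )
    if denom == 0:
        pct = 0.0
    else:
        pct = 100.0 * emission_saving / denom
    return ComparisonReport(
        row_deltas=deltas,
        emission_saving=emission_saving,
        sink_gain=sink_gain,
        emission_reduction_percent=pct,
        credit_change=scenario.carbon_credit - base.carbon_credit,
    )
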