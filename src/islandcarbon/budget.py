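"""Annual carbon-budget accounting: emissions, sinks, credit, shares.

One simulated year of process fluxes is aggregated into a two-column
budget table (carbon emission / carbon sink, both tC/yr).  The mapping
from the 24 process fluxes to budget rows is explicit and total: every
flux must be assigned to exactly one row (possibly summed or netted with
others) or declared internal; an unmapped flux is an error, never silently
dropped.

Conventions carried by the default mapping:

* the private-car row sums resident cars (pc) and tourist cars (car);
  rental motorcycles keep their own row;
* ecosystem rows are net annual fluxes: forest = f_pho - f_res -
  decomposition, wetland = w_pho - w_res - wet_ch4_release -
  litter_to_sea;
* the soil-respiration row carries the magnitude of the soil-uptake
  (adsorption) pathway but is classified as an emission, the convention
  of the reference budget for this island; the classification lives in
  the mapping and can be changed there;
* the uncaptured landfill CH4 transfer is internal (the solid-waste row
  already carries the landfill CH4 generation).

The island's *carbon credit* is total emission minus total sink; negative
means the island removes more carbon than it releases.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
import json

import pandas as pd

from .integrate import Trajectory
from .model import FLUX_NAMES

__all__ = [
    "BudgetMapping",
    "BudgetRow",
    "BudgetTable",
    "RowSpec",
    "DEFAULT_MAPPING",
    "MappingError",
    "UndefinedShareError",
    "aggregate",
    "carbon_credit",
    "shares",
    "round_to_ten",
    "round_share",
]


class MappingError(ValueError):
    """The flux-to-row mapping is not total or references unknown fluxes."""


class UndefinedShareError(ZeroDivisionError):
    """Percentage shares are undefined because a column total is zero."""


def round_to_ten(value: float) -> int:
    """Round to the nearest 10 tC/yr, half away from zero (table precision)."""
    return int(Decimal(repr(value / 10.0)).quantize(0, rounding=ROUND_HALF_UP)) * 10


def round_share(value: float) -> float:
    """Round a percentage to one decimal place, half up."""
    return float(Decimal(repr(value)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class RowSpec:
    """One budget row: its column and the signed fluxes netted into it."""

    name: str
    column: str  # "emission" | "sink"
    terms: tuple[tuple[str, int], ...]  # (flux name, +1 | -1)

    def value(self, totals: dict[str, float]) -> float:
        return sum(sign * totals[name] for name, sign in self.terms)


@dataclass(frozen=True)
class BudgetMapping:
    """Total assignment of every process flux to a budget row or internal."""

    rows: tuple[RowSpec, ...]
    internal: frozenset[str]

    def validate(self) -> None:
        seen: dict[str, str] = {}
        for row in self.rows:
            if row.column not in ("emission", "sink"):
                raise MappingError(
                    f"row {row.name!r}: column must be emission or sink"
                )
            for flux, sign in row.terms:
                if flux not in FLUX_NAMES:
                    raise MappingError(f"row {row.name!r}: unknown flux {flux!r}")
                if sign not in (1, -1):
                    raise MappingError(f"row {row.name!r}: sign must be +1/-1")
                if flux in seen:
                    raise MappingError(
                        f"flux {flux!r} mapped twice ({seen[flux]!r} and {row.name!r})"
                    )
                seen[flux] = row.name
        for flux in self.internal:
            if flux not in FLUX_NAMES:
                raise MappingError(f"internal list references unknown flux {flux!r}")
            if flux in seen:
                raise MappingError(
                    f"flux {flux!r} both internal and mapped to {seen[flux]!r}"
                )
            seen[flux] = "(internal)"
        missing = sorted(set(FLUX_NAMES) - set(seen))
        if missing:
            raise MappingError(f"fluxes not mapped to any budget row: {missing}")

    def to_dict(self) -> dict:
        return {
            "rows": [
                {"name": r.name, "column": r.column,
                 "terms": [[f, s] for f, s in r.terms]}
                for r in self.rows
            ],
            "internal": sorted(self.internal),
        }


def _row(name: str, column: str, *terms: str | tuple[str, int]) -> RowSpec:
    norm = tuple((t, 1) if isinstance(t, str) else t for t in terms)
    return RowSpec(name, column, norm)


DEFAULT_MAPPING = BudgetMapping(
    rows=(
        _row("ferry", "emission", "ferry"),
        _row("small_shuttle_bus", "emission", "ssb"),
        _row("private_car", "emission", "pc", "car"),
        _row("rental_motorcycle", "emission", "rm"),
        _row("fishing", "emission", "fishing"),
        _row("visiting", "emission", "visiting"),
        _row("water_activity", "emission", "wa"),
        _row("shopping", "emission", "shopping"),
        _row("hotel", "emission", "hotel"),
        _row("private_home", "emission", "ph"),
        _row("desalination", "emission", "desalination"),
        _row("mussel_aquaculture_activity", "emission", "aquaculture"),
        _row("soil_respiration", "emission", "adsorption"),
        _row("solid_waste", "emission", "waste"),
        _row("shell_aquaculture", "sink", "sg"),
        _row("forest_ecosystem", "sink", "f_pho", ("f_res", -1),
             ("decomposition", -1)),
        _row("wetland_ecosystem", "sink", "w_pho", ("w_res", -1),
             ("wet_ch4_release", -1), ("litter_to_sea", -1)),
    ),
    internal=frozenset({"unused_ch4"}),
)
DEFAULT_MAPPING.validate()

#: human-readable row labels for the text rendering
ROW_LABELS: dict[str, str] = {
    "ferry": "Ferry",
    "small_shuttle_bus": "Small shuttle bus",
    "private_car": "Private car",
    "rental_motorcycle": "Rental motorcycle",
    "fishing": "Fishing",
    "visiting": "Visiting",
    "water_activity": "Water activity",
    "shopping": "Shopping",
    "hotel": "Hotel",
    "private_home": "Private home",
    "desalination": "Desalination",
    "mussel_aquaculture_activity": "Mussel aquaculture activity",
    "soil_respiration": "Soil respiration",
    "solid_waste": "Solid waste",
    "shell_aquaculture": "Shell aquaculture",
    "forest_ecosystem": "Forest ecosystem",
    "wetland_ecosystem": "Wetland ecosystem",
}


@dataclass(frozen=True)
class BudgetRow:
    name: str
    column: str  # "emission" | "sink"
    value: float  # tC/yr


@dataclass(frozen=True)
class BudgetTable:
    """Annual budget: rows, column totals, carbon credit.

    ``headline_emission`` optionally overrides the emission total used as
    the denominator of percentage shares (and only for shares), for
    reporting against an externally fixed headline total.
    """

    rows: tuple[BudgetRow, ...]
    mapping: BudgetMapping | None = None
    headline_emission: float | None = None

    @property
    def total_emission(self) -> float:
        return sum(r.value for r in self.rows if r.column == "emission")

    @property
    def total_sink(self) -> float:
        return sum(r.value for r in self.rows if r.column == "sink")

    @property
    def carbon_credit(self) -> float:
        return carbon_credit(self.total_emission, self.total_sink)

    def row(self, name: str) -> BudgetRow:
        for r in self.rows:
            if r.name == name:
                return r
        raise KeyError(name)

    def with_headline_emission(self, total: float | None) -> "BudgetTable":
        return replace(self, headline_emission=total)

    # ---- export ----------------------------------------------------------
    def to_frame(self, rounded: bool = False) -> pd.DataFrame:
        df = pd.DataFrame(
            [(r.name, r.column, round_to_ten(r.value) if rounded else r.value)
             for r in self.rows],
            columns=["row", "column", "tC_per_yr"],
        )
        return df

    def to_csv(self, path: str | Path, rounded: bool = False) -> None:
        self.to_frame(rounded=rounded).to_csv(path, index=False)

    def report(self) -> dict:
        """JSON-ready report: rows, totals, credit, shares, mapping."""
        return {
            "rows": [
                {"name": r.name, "column": r.column, "tC_per_yr": r.value,
                 "rounded": round_to_ten(r.value)}
                for r in self.rows
            ],
            "total_emission": self.total_emission,
            "total_sink": self.total_sink,
            "carbon_credit": self.carbon_credit,
            "headline_emission": self.headline_emission,
            "shares_percent": shares(self),
            "mapping": self.mapping.to_dict() if self.mapping else None,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.report(), indent=2, sort_keys=True))

    def render_text(self) -> str:
        """Aligned two-column rendering (values rounded to the nearest 10)."""
        lines = [f"{'Item':32s} {'Emission (tC/yr)':>18s} {'Sink (tC/yr)':>14s}"]
        for r in self.rows:
            label = ROW_LABELS.get(r.name, r.name)
            v = round_to_ten(r.value)
            if r.column == "emission":
                lines.append(f"{label:32s} {v:>18d} {'':>14s}")
            else:
                lines.append(f"{label:32s} {'':>18s} {v:>14d}")
        lines.append(
            f"{'Total':32s} {round_to_ten(self.total_emission):>18d} "
            f"{round_to_ten(self.total_sink):>14d}"
        )
        lines.append(f"Carbon credit: {round_to_ten(self.carbon_credit)} tC/yr")
        return "\n".join(lines)


def carbon_credit(total_emission: float, total_sink: float) -> float:
    """Net annual balance, emission minus sink; negative = net removal."""
    if total_emission < 0 or total_sink < 0:
        raise ValueError("column totals must be non-negative")
    return total_emission - total_sink


def shares(table: BudgetTable) -> dict[str, float]:
    """Per-row percentage of its column total, to 0.1 % (half-up).

    Uses ``table.headline_emission`` as the emission denominator when set.
    """
    e_total = (
        table.headline_emission
        if table.headline_emission is not None
        else table.total_emission
    )
    s_total = table.total_sink
    out: dict[str, float] = {}
    for r in table.rows:
        denom = e_total if r.column == "emission" else s_total
        if denom == 0:
            raise UndefinedShareError(
                f"share of row {r.name!r} undefined: {r.column} total is zero"
            )
        out[r.name] = round_share(100.0 * r.value / denom)
    return out


def aggregate(
    trajectory: Trajectory,
    mapping: BudgetMapping = DEFAULT_MAPPING,
    headline_emission: float | None = None,
) -> BudgetTable:
    """Aggregate exactly one simulated year of fluxes into a budget table.

    Extra pass-through emission terms and added sink projects declared in
    the run config appear as their own rows.
    """
    mapping.validate()
    if abs(trajectory.horizon - 1.0) > 1e-9:
        raise ValueError(
            f"budget aggregation needs a one-year trajectory, got "
            f"{trajectory.horizon} yr"
        )
    totals = trajectory.flux_totals()  # tC over one year == mean tC/yr
    rows = [
        BudgetRow(spec.name, spec.column, spec.value(totals))
        for spec in mapping.rows
    ]
    cfg = trajectory.config
    for name, rate in cfg.extra_emissions.items():
        rows.append(BudgetRow(name, "emission", rate))
    for sink in cfg.added_sinks:
        rows.append(BudgetRow(sink.name, "sink", sink.annual_tc))
    return BudgetTable(
        rows=tuple(rows), mapping=mapping, headline_emission=headline_emission
    )
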