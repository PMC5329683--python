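"""Fixed-step integration of the stock-and-flow equations.

Stocks advance by the explicit (Euler) rule: each step evaluates all 24
fluxes from the state at the start of the step, then updates every stock
by (inflows - outflows) * dt.  This deliberately mirrors the difference
equations of visual stock-and-flow environments rather than an adaptive
ODE solver — the difference equations, not their continuum limit, are the
model.

Inflow/outflow membership per stock:

    co2_exchange += (w_res + f_res + aquaculture + pc + desalination
                     + shopping + wa + visiting + fishing + hotel + ph
                     + ferry + rm + car + ssb
                     - w_pho - f_pho - adsorption - sg) * dt
    forest_c     += (f_pho - f_res - decomposition) * dt
    wetland_c    += (w_pho - w_res - litter_to_sea - wet_ch4_release) * dt
    shell_c      += sg * dt
    soil_c       += (adsorption + decomposition) * dt
    waste_ch4    += (waste - unused_ch4) * dt
    total_ch4    += (wet_ch4_release + unused_ch4) * dt

Named extra emission terms from the config enter co2_exchange alongside
the person-driven inflows.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .config import ModelConfig, config_hash
from .model import (
    CarbonPools,
    FluxSet,
    FLUX_NAMES,
    FLUX_ROLES,
    compute_fluxes,
)

logger = logging.getLogger(__name__)

__all__ = ["Trajectory", "step", "run", "IntegrationError"]


class IntegrationError(RuntimeError):
    """The integration produced an invalid state; names the offender."""


# stock -> (inflow fluxes, outflow fluxes); co2_exchange handled separately
_STOCK_FLOWS: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = {
    "forest_c": (("f_pho",), ("f_res", "decomposition")),
    "wetland_c": (("w_pho",), ("w_res", "litter_to_sea", "wet_ch4_release")),
    "shell_c": (("sg",), ()),
    "soil_c": (("adsorption", "decomposition"), ()),
    "waste_ch4": (("waste",), ("unused_ch4",)),
    "total_ch4": (("wet_ch4_release", "unused_ch4"), ()),
}

_CO2_INFLOWS: tuple[str, ...] = (
    "w_res", "f_res", "aquaculture", "pc", "desalination", "shopping", "wa",
    "visiting", "fishing", "hotel", "ph", "ferry", "rm", "car", "ssb",
)
_CO2_OUTFLOWS: tuple[str, ...] = ("w_pho", "f_pho", "adsorption", "sg")

#: fluxes crossing the system boundary (for mass-conservation accounting):
#: emission-role fluxes enter from outside; litter export leaves to the sea.
EXTERNAL_IN: tuple[str, ...] = tuple(
    n for n in FLUX_NAMES if FLUX_ROLES[n] == "emission"
)
EXTERNAL_OUT: tuple[str, ...] = ("litter_to_sea",)


def step(
    pools: CarbonPools,
    fluxes: FluxSet,
    dt: float,
    negative_stock: Literal["floor", "error"] = "floor",
    extra_emission_rate: float = 0.0,
) -> CarbonPools:
    """Advance all stocks one step of length ``dt`` years.

    When an outflow would overdraw a non-negative stock within the step,
    the stock is floored at zero with a logged warning (default) or an
    :class:`IntegrationError` is raised (``negative_stock="error"``).
    """
    if dt <= 0:
        raise ValueError(f"dt={dt} must be positive")
    f = fluxes.as_dict()
    new: dict[str, float] = {}
    co2_rate = (
        sum(f[n] for n in _CO2_INFLOWS)
        + extra_emission_rate
        - sum(f[n] for n in _CO2_OUTFLOWS)
    )
    new["co2_exchange"] = pools.co2_exchange + co2_rate * dt
    for stock, (inflows, outflows) in _STOCK_FLOWS.items():
        rate = sum(f[n] for n in inflows) - sum(f[n] for n in outflows)
        value = getattr(pools, stock) + rate * dt
        if value < 0.0:
            if negative_stock == "error":
                raise IntegrationError(
                    f"stock {stock!r} overdrawn to {value!r} within one step"
                )
            logger.warning(
                "stock %s overdrawn to %s within one step; flooring at 0",
                stock, value,
            )
            value = 0.0
        new[stock] = value
    return CarbonPools(**new)


@dataclass(frozen=True)
class Trajectory:
    """Recorded run: times (years), one state per time, one flux set per step.

    ``times`` has n+1 entries on a uniform grid; ``states[i]`` is the state
    at ``times[i]``; ``fluxes[i]`` was evaluated from ``states[i]`` and
    advanced the system to ``states[i+1]``.
    """

    times: np.ndarray
    states: tuple[CarbonPools, ...]
    fluxes: tuple[FluxSet, ...]
    config: ModelConfig
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.states) != len(self.times):
            raise ValueError("states and times must align one-to-one")
        if len(self.fluxes) != len(self.times) - 1:
            raise ValueError("need exactly one flux set per step")
        dts = np.diff(self.times)
        if len(dts) and (dts.min() <= 0 or not np.allclose(dts, dts[0], rtol=1e-9)):
            raise ValueError("times must be strictly increasing with constant step")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def horizon(self) -> float:
        return float(self.times[-1] - self.times[0])

    def flux_totals(self) -> dict[str, float]:
        """Time-integrated flux totals over the run, in tC (sum flux * dt)."""
        dt = self.dt
        totals = dict.fromkeys(FLUX_NAMES, 0.0)
        for fs in self.fluxes:
            for name, v in fs.as_dict().items():
                totals[name] += v * dt
        return totals

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format table: time, kind (stock/flux), name, value, unit."""
        records: list[tuple[float, str, str, float, str]] = []
        for t, st in zip(self.times, self.states):
            for name, v in st.model_dump().items():
                records.append((float(t), "stock", name, v, "tC"))
        for t, fs in zip(self.times[:-1], self.fluxes):
            for name, v in fs.as_dict().items():
                records.append((float(t), "flux", name, v, "tC yr-1"))
        return pd.DataFrame(
            records, columns=["time", "kind", "name", "value", "unit"]
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def _check_finite_state(pools: CarbonPools, step_index: int) -> None:
    for name, v in pools.model_dump().items():
        if not math.isfinite(v):
            raise IntegrationError(
                f"non-finite stock {name!r} = {v!r} after step {step_index}"
            )


def run(config: ModelConfig, seed: int | None = None) -> Trajectory:
    """Run the model over ``config.horizon`` years with step ``config.dt``.

    The model itself is deterministic; ``seed`` is recorded in the run log
    and trajectory metadata so that runs driven by randomized configs stay
    traceable.  Aborts with a diagnostic naming the offending flux or stock
    if a non-finite value appears.
    """
    n_steps = round(config.horizon / config.dt)
    if n_steps < 1 or abs(n_steps * config.dt - config.horizon) > 1e-9:
        raise ValueError(
            f"horizon {config.horizon} is not a whole number of steps of "
            f"dt={config.dt}"
        )
    chash = config_hash(config)
    logger.info(
        "run start: config=%s hash=%s seed=%s dt=%s horizon=%s",
        config.name, chash, seed, config.dt, config.horizon,
    )
    extra_rate = sum(config.extra_emissions.values())
    pools = config.initial_stocks
    times = [0.0]
    states = [pools]
    flux_log: list[FluxSet] = []
    for i in range(n_steps):
        fluxes = compute_fluxes(
            pools,
            config.profile,
            config.forcings,
            config.parameters,
            config.constants,
            config.temp_mode,
        )
        if config.flux_multipliers:
            fluxes = fluxes.scaled(config.flux_multipliers)
        pools = step(
            pools,
            fluxes,
            config.dt,
            negative_stock=config.negative_stock,
            extra_emission_rate=extra_rate,
        )
        _check_finite_state(pools, i)
        flux_log.append(fluxes)
        states.append(pools)
        times.append((i + 1) * config.dt)
    logger.info("run done: config=%s hash=%s steps=%d", config.name, chash, n_steps)
    return Trajectory(
        times=np.asarray(times),
        states=tuple(states),
        fluxes=tuple(flux_log),
        config=config,
        metadata={"config_hash": chash, "seed": seed},
    )
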