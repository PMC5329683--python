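"""Domain types and process fluxes of the island carbon-cycle model.

The model is a stock-and-flow description of a small inhabited island:
seven carbon stocks (an atmospheric-exchange accumulator, forest, wetland,
mussel shell, soil, landfill CH4 and cumulative CH4) connected by 24 named
process fluxes.  Human carbon sources are driven by visitor and resident
person-days (ferry crossings, island transport, lodging, desalination,
waste); natural fluxes (photosynthesis, respiration, soil uptake, litter
export, wetland CH4) are first-order in their driving stock with saturating
light and simple temperature response.  Shellfish aquaculture appears twice:
as a fossil-fuel emission of the industry and as a carbonate sink, mussels
fixing shell carbon from dissolved bicarbonate (Ca2+ + 2HCO3- -> CaCO3 +
CO2 + H2O).

Every flux is expressed in tonnes of carbon per year (tC/yr) and every
stock in tonnes of carbon (tC).  Per-unit emission coefficients keep the
unit they are reported in (g CO2 or g CH4 per activity unit) and are
converted at the flux boundary (12/44 per g CO2, 12/16 per g CH4).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, fields as dataclass_fields
from typing import Literal, Mapping

from pydantic import BaseModel, ConfigDict, Field, model_validator

logger = logging.getLogger(__name__)

__all__ = [
    "CarbonPools",
    "Forcings",
    "TouristProfile",
    "IslandParameters",
    "ModelConstants",
    "CONSTANTS",
    "FluxSet",
    "FLUX_NAMES",
    "FLUX_ROLES",
    "DomainError",
    "FluxError",
    "g_co2_to_tc",
    "tc_to_g_co2",
    "g_ch4_to_tc",
    "visitor_activity_days",
    "lodging_nights",
    "tourism_fluxes",
    "infrastructure_fluxes",
    "ecosystem_fluxes",
    "aquaculture_fluxes",
    "ch4_fluxes",
    "compute_fluxes",
    "forest_area",
    "tidal_area",
    "aqu_area",
]


class DomainError(ValueError):
    """A model quantity left its physically meaningful domain."""


class FluxError(ValueError):
    """A computed flux is negative or non-finite; names the offending flux."""


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------

class _Frozen(BaseModel):
    model_config = ConfigDict(frozen=True, extra="forbid")


class CarbonPools(_Frozen):
    """The seven model stocks, all in tonnes of carbon.

    ``co2_exchange`` is the cumulative net carbon released to the
    atmosphere (emissions minus captures) and may take either sign; the
    remaining stocks are physical pools and must stay non-negative.
    """

    co2_exchange: float = 0.0
    forest_c: float = Field(default=0.0, ge=0.0)
    wetland_c: float = Field(default=0.0, ge=0.0)
    shell_c: float = Field(default=0.0, ge=0.0)
    soil_c: float = Field(default=0.0, ge=0.0)
    waste_ch4: float = Field(default=0.0, ge=0.0)
    total_ch4: float = Field(default=0.0, ge=0.0)

    def total(self) -> float:
        """Sum of all stocks (used by the mass-conservation check)."""
        return (
            self.co2_exchange + self.forest_c + self.wetland_c + self.shell_c
            + self.soil_c + self.waste_ch4 + self.total_ch4
        )


class Forcings(_Frozen):
    """Externally prescribed drivers, constant over a simulated year.

    temp: mean air temperature (degC); rade: mean solar radiation
    (MJ m-2 yr-1); nv / ni: visitors per year and resident inhabitants;
    land_area and inshore_area in km2.
    """

    temp: float
    rade: float = Field(gt=0.0)
    nv: float = Field(ge=0.0)
    ni: float = Field(ge=0.0)
    land_area: float = Field(gt=0.0)
    inshore_area: float = Field(gt=0.0)


class TouristProfile(_Frozen):
    """Stay-duration distribution and on-island behaviour of visitors.

    ``sd`` holds the fractions of visitors staying 1, 2, 3, 4 and 5+ days;
    they must sum to one.  Lodging fractions split overnight visitors
    between hotels and private homes; modal fractions give the shares
    using rental motorcycles, private cars and the small shuttle bus, with
    their mean daily travel distances in km/day.
    """

    sd: tuple[float, float, float, float, float]
    hotel_r: float = Field(ge=0.0, le=1.0)
    ph_r: float = Field(ge=0.0, le=1.0)
    moto_r: float = Field(ge=0.0, le=1.0)
    pc_r: float = Field(ge=0.0, le=1.0)
    ssd_r: float = Field(ge=0.0, le=1.0)
    pd_moto: float = Field(ge=0.0)
    pd_pc: float = Field(ge=0.0)
    pd_ssd: float = Field(ge=0.0)

    @model_validator(mode="after")
    def _check_sd(self) -> "TouristProfile":
        for i, f in enumerate(self.sd, start=1):
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"sd{i}={f} outside [0, 1]")
        s = math.fsum(self.sd)
        if abs(s - 1.0) > 1e-9:
            raise ValueError(
                f"stay-duration fractions sd1..sd5 must sum to 1, got {s!r}"
            )
        return self


class IslandParameters(_Frozen):
    """Rate constants and per-unit emission coefficients.

    Emission coefficients ``ce_*`` are in grams of CO2 per activity unit
    (per km, per night, per tonne of water, per visitor-hour ...) except
    where noted; they are converted to tC at the flux boundary.  Ecosystem
    rates are first-order coefficients acting on a stock in tC (per year,
    per km2 of habitat and per degC below the reference temperature where
    the corresponding formula says so).  ``ce_car`` is the annual emission
    of one resident car; ``ce_pc`` is the per-km coefficient of a tourist
    car driven on the island.
    """

    # ecosystem first-order rates
    w_growth_r: float = Field(ge=0.0)
    f_growth_r: float = Field(ge=0.0)
    w_re_r: float = Field(ge=0.0)
    f_re_r: float = Field(ge=0.0)
    dec_r: float = Field(ge=0.0)
    ads_r: float = Field(ge=0.0)
    # land/sea use as fractions of the forcing areas
    forest_frac: float = Field(ge=0.0, le=1.0)
    tidal_frac: float = Field(ge=0.0, le=1.0)
    aqu_frac: float = Field(ge=0.0, le=1.0)
    # mussel growth and shell carbon
    growth_r: float = Field(ge=0.0, description="mussel growth, mg C m-2 yr-1")
    shell_c_r: float = Field(ge=0.0, le=1.0)
    # emission coefficients (g CO2 per unit unless stated)
    ce_aqu: float = Field(ge=0.0, description="g CO2 km-2 yr-1 of culture area")
    ce_car: float = Field(ge=0.0, description="g CO2 car-1 yr-1 (resident cars)")
    ce_desalination: float = Field(ge=0.0, description="g CO2 t-1 fresh water")
    ce_ferry: float = Field(ge=0.0, description="g CO2 km-1")
    ce_fishing: float = Field(ge=0.0, description="g CO2 per visitor-day")
    ce_hotel: float = Field(ge=0.0, description="g CO2 per night")
    ce_moto: float = Field(ge=0.0, description="g CO2 km-1")
    ce_pc: float = Field(ge=0.0, description="g CO2 km-1 (tourist cars)")
    ce_ph: float = Field(ge=0.0, description="g CO2 per night")
    ce_shopping: float = Field(ge=0.0, description="g CO2 per visitor-day")
    ce_ssb: float = Field(ge=0.0, description="g CO2 km-1")
    ce_visiting: float = Field(ge=0.0, description="g CO2 per visitor-day")
    ce_wa: float = Field(ge=0.0, description="g CO2 per visitor-day")
    # infrastructure / waste
    dis_ferry: float = Field(ge=0.0, description="km per visitor (round trip)")
    per_wc: float = Field(ge=0.0, description="t water person-1 day-1")
    per_waste: float = Field(ge=0.0, description="kg waste person-1 day-1")
    pch4_waste: float = Field(ge=0.0, description="g CH4 kg-1 waste")
    ch4_use_r: float = Field(ge=0.0, le=1.0)
    car_r: float = Field(ge=0.0, le=1.0, description="resident car ownership")


class ModelConstants(_Frozen):
    """Fixed named constants of the process formulas.

    These are structural: the reference temperature appearing in every
    (ref_temp - temp) factor, the base of the exponential temperature
    response, the half-saturation and scale of the Michaelis-Menten light
    factor, the carbonate-chemistry divisor of the shell-growth flux, the
    litter-export and wetland-CH4 fractions, and the molar mass ratios used
    for gas-to-carbon conversion.  They are never re-tuned silently.
    """

    ref_temp: float = 20.0
    q_base: float = 1.05
    light_half_sat: float = 6.0
    light_scale: float = 690.0
    shell_carbon_divisor: float = 0.27
    litter_to_sea_frac: float = 0.5
    wetland_ch4_frac: float = 0.1
    co2_to_c: float = 12.0 / 44.0
    ch4_to_c: float = 12.0 / 16.0
    days_per_year: float = 365.0


CONSTANTS = ModelConstants()

# --------------------------------------------------------------------------
# Flux container
# --------------------------------------------------------------------------

FLUX_NAMES: tuple[str, ...] = (
    "w_res", "f_res", "aquaculture", "pc", "desalination", "shopping", "wa",
    "visiting", "fishing", "hotel", "ph", "ferry", "rm", "car", "ssb",
    "w_pho", "f_pho", "adsorption", "sg", "decomposition",
    "wet_ch4_release", "unused_ch4", "waste", "litter_to_sea",
)

#: role of each flux in the island budget: ``emission`` terms enter the
#: atmospheric-exchange stock from outside the island system, ``sink``
#: terms remove carbon from it into island stocks, ``internal`` terms move
#: carbon between stocks (or export it to the sea, for litter_to_sea).
FLUX_ROLES: Mapping[str, str] = {
    "aquaculture": "emission", "pc": "emission", "desalination": "emission",
    "shopping": "emission", "wa": "emission", "visiting": "emission",
    "fishing": "emission", "hotel": "emission", "ph": "emission",
    "ferry": "emission", "rm": "emission", "car": "emission",
    "ssb": "emission", "waste": "emission",
    "w_pho": "sink", "f_pho": "sink", "adsorption": "sink", "sg": "sink",
    "w_res": "internal", "f_res": "internal", "decomposition": "internal",
    "wet_ch4_release": "internal", "unused_ch4": "internal",
    "litter_to_sea": "internal",
}


@dataclass(frozen=True)
class FluxSet:
    """The 24 process fluxes, each in tC/yr, all non-negative.

    Signs live in the stock-update rule and in the role tags, never in the
    values themselves.
    """

    w_res: float = 0.0
    f_res: float = 0.0
    aquaculture: float = 0.0
    pc: float = 0.0
    desalination: float = 0.0
    shopping: float = 0.0
    wa: float = 0.0
    visiting: float = 0.0
    fishing: float = 0.0
    hotel: float = 0.0
    ph: float = 0.0
    ferry: float = 0.0
    rm: float = 0.0
    car: float = 0.0
    ssb: float = 0.0
    w_pho: float = 0.0
    f_pho: float = 0.0
    adsorption: float = 0.0
    sg: float = 0.0
    decomposition: float = 0.0
    wet_ch4_release: float = 0.0
    unused_ch4: float = 0.0
    waste: float = 0.0
    litter_to_sea: float = 0.0

    def __post_init__(self) -> None:
        for name in FLUX_NAMES:
            v = getattr(self, name)
            if not math.isfinite(v):
                raise FluxError(f"flux {name!r} is non-finite: {v!r}")
            if v < 0.0:
                raise FluxError(f"flux {name!r} is negative: {v!r}")

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in FLUX_NAMES}

    def scaled(self, multipliers: Mapping[str, float]) -> "FluxSet":
        """Return a copy with per-flux multipliers applied."""
        unknown = set(multipliers) - set(FLUX_NAMES)
        if unknown:
            raise KeyError(f"unknown flux names in multipliers: {sorted(unknown)}")
        d = self.as_dict()
        for name, m in multipliers.items():
            d[name] *= m
        return FluxSet(**d)

    def role(self, name: str) -> str:
        return FLUX_ROLES[name]


assert set(f.name for f in dataclass_fields(FluxSet)) == set(FLUX_NAMES)
assert set(FLUX_ROLES) == set(FLUX_NAMES)


# --------------------------------------------------------------------------
# Unit conversions and derived areas
# --------------------------------------------------------------------------

_G_PER_T = 1e6


def g_co2_to_tc(grams_co2: float, constants: ModelConstants = CONSTANTS) -> float:
    """Grams of CO2 to tonnes of carbon (12/44 molar mass ratio)."""
    return grams_co2 / _G_PER_T * constants.co2_to_c


def tc_to_g_co2(tc: float, constants: ModelConstants = CONSTANTS) -> float:
    """Tonnes of carbon back to grams of CO2; inverse of :func:`g_co2_to_tc`."""
    return tc * _G_PER_T / constants.co2_to_c


def g_ch4_to_tc(grams_ch4: float, constants: ModelConstants = CONSTANTS) -> float:
    """Grams of CH4 to tonnes of (methane-) carbon (12/16)."""
    return grams_ch4 / _G_PER_T * constants.ch4_to_c


def forest_area(params: IslandParameters, forcings: Forcings) -> float:
    """Forested area in km2 (fraction of island land area)."""
    return params.forest_frac * forcings.land_area


def tidal_area(params: IslandParameters, forcings: Forcings) -> float:
    """Tidal-wetland area in km2 (fraction of island land area)."""
    return params.tidal_frac * forcings.land_area


def aqu_area(params: IslandParameters, forcings: Forcings) -> float:
    """Mussel-culture area in km2 (fraction of managed inshore sea)."""
    return params.aqu_frac * forcings.inshore_area


# --------------------------------------------------------------------------
# Person-day weights
# --------------------------------------------------------------------------

def visitor_activity_days(profile: TouristProfile, nv: float) -> float:
    """Total visitor activity person-days per year.

    A visitor staying k days contributes k activity days, so the total is
    nv * sum(k * sd_k) over the stay-duration distribution.
    """
    if nv < 0:
        raise DomainError(f"visitor count nv={nv} must be non-negative")
    return nv * math.fsum(k * f for k, f in enumerate(profile.sd, start=1))


def lodging_nights(profile: TouristProfile, nv: float) -> float:
    """Total visitor lodging person-nights per year.

    A k-day stay implies k - 1 nights; day-trippers lodge zero nights.
    """
    if nv < 0:
        raise DomainError(f"visitor count nv={nv} must be non-negative")
    return nv * math.fsum((k - 1) * f for k, f in enumerate(profile.sd, start=1))


# --------------------------------------------------------------------------
# Flux groups
# --------------------------------------------------------------------------

def tourism_fluxes(
    profile: TouristProfile,
    forcings: Forcings,
    params: IslandParameters,
    constants: ModelConstants = CONSTANTS,
) -> dict[str, float]:
    """Visitor-behaviour emissions: activities, lodging and island transport.

    Activity fluxes scale with activity person-days, lodging fluxes with
    person-nights x lodging share, transport fluxes additionally with the
    modal share and daily distance.  All returned in tC/yr.
    """
    act = visitor_activity_days(profile, forcings.nv)
    nights = lodging_nights(profile, forcings.nv)
    return {
        "shopping": g_co2_to_tc(act * params.ce_shopping, constants),
        "wa": g_co2_to_tc(act * params.ce_wa, constants),
        "visiting": g_co2_to_tc(act * params.ce_visiting, constants),
        "fishing": g_co2_to_tc(act * params.ce_fishing, constants),
        "hotel": g_co2_to_tc(nights * profile.hotel_r * params.ce_hotel, constants),
        "ph": g_co2_to_tc(nights * profile.ph_r * params.ce_ph, constants),
        "rm": g_co2_to_tc(
            act * profile.moto_r * profile.pd_moto * params.ce_moto, constants
        ),
        "car": g_co2_to_tc(
            act * profile.pd_pc * profile.pc_r * params.ce_pc, constants
        ),
        "ssb": g_co2_to_tc(
            act * profile.pd_ssd * profile.ssd_r * params.ce_ssb, constants
        ),
    }


def infrastructure_fluxes(
    profile: TouristProfile,
    forcings: Forcings,
    params: IslandParameters,
    constants: ModelConstants = CONSTANTS,
) -> dict[str, float]:
    """Resident and shared-infrastructure emissions.

    Desalination and solid waste are driven by total person-days (visitor
    activity days plus 365 x residents); the ferry by visitor crossings;
    resident private cars by the car-ownership fraction.  ``waste`` is
    landfill CH4 expressed as carbon (12/16).
    """
    act = visitor_activity_days(profile, forcings.nv)
    person_days = act + constants.days_per_year * forcings.ni
    return {
        "pc": g_co2_to_tc(params.car_r * forcings.ni * params.ce_car, constants),
        "desalination": g_co2_to_tc(
            person_days * params.per_wc * params.ce_desalination, constants
        ),
        "ferry": g_co2_to_tc(
            forcings.nv * params.dis_ferry * params.ce_ferry, constants
        ),
        "waste": g_ch4_to_tc(
            person_days * params.per_waste * params.pch4_waste, constants
        ),
    }


def _linear_temp_factor(
    temp: float,
    constants: ModelConstants,
    temp_mode: Literal["clamp", "strict"],
) -> float:
    """The (ref_temp - temp) factor of respiration/uptake formulas.

    The formulas were written for a climate colder than the 20 degC
    reference; above it the linear factor would turn respiration negative,
    so it is clamped at zero (with a warning) unless strict mode is on.
    """
    f = constants.ref_temp - temp
    if f < 0.0:
        if temp_mode == "strict":
            raise DomainError(
                f"temp={temp} exceeds the reference temperature "
                f"{constants.ref_temp}; the linear temperature factor is "
                "undefined (strict mode)"
            )
        logger.warning(
            "temp=%s >= ref_temp=%s: clamping linear temperature factor to 0",
            temp, constants.ref_temp,
        )
        return 0.0
    return f


def ecosystem_fluxes(
    pools: CarbonPools,
    forcings: Forcings,
    params: IslandParameters,
    constants: ModelConstants = CONSTANTS,
    temp_mode: Literal["clamp", "strict"] = "clamp",
) -> dict[str, float]:
    """Forest, wetland and soil fluxes, all first-order in their stock.

    Photosynthesis combines an exponential temperature response
    q_base**(ref_temp - temp) with a saturating light factor
    rade / (rade + K) * scale; respiration, decomposition and soil uptake
    use the linear (ref_temp - temp) factor.
    """
    lin = _linear_temp_factor(forcings.temp, constants, temp_mode)
    q = constants.q_base ** (constants.ref_temp - forcings.temp)
    light = forcings.rade / (forcings.rade + constants.light_half_sat) \
        * constants.light_scale
    t_area = tidal_area(params, forcings)
    f_area = forest_area(params, forcings)
    return {
        "w_pho": pools.wetland_c * params.w_growth_r * t_area * q * light,
        "f_pho": pools.forest_c * params.f_growth_r * f_area * q * light,
        "w_res": params.w_re_r * t_area * lin * pools.wetland_c,
        "f_res": pools.forest_c * f_area * params.f_re_r * lin,
        "adsorption": pools.soil_c * params.ads_r * lin,
        "decomposition": pools.forest_c * params.dec_r * lin,
        "litter_to_sea": constants.litter_to_sea_frac * pools.wetland_c,
        "wet_ch4_release": constants.wetland_ch4_frac * pools.wetland_c * lin,
    }


def aquaculture_fluxes(
    forcings: Forcings,
    params: IslandParameters,
    constants: ModelConstants = CONSTANTS,
) -> dict[str, float]:
    """Mussel-culture emission and shell-carbonate sink.

    The industry emission is proportional to culture area (coefficient in
    g CO2 per km2).  Shell growth fixes carbon at
    area[m2] * growth_r[mg C m-2 yr-1] * shell_c_r / shell_carbon_divisor;
    the divisor reflects the carbonate chemistry in which roughly 0.27 of
    the bicarbonate carbon ends up in shell.
    """
    area_km2 = aqu_area(params, forcings)
    area_m2 = area_km2 * 1e6
    growth_g = params.growth_r * 1e-3  # mg -> g C m-2 yr-1
    sg_grams = area_m2 * growth_g * params.shell_c_r / constants.shell_carbon_divisor
    return {
        "aquaculture": g_co2_to_tc(area_km2 * params.ce_aqu, constants),
        "sg": sg_grams / _G_PER_T,
    }


def ch4_fluxes(
    pools: CarbonPools,
    forcings: Forcings,
    params: IslandParameters,
    constants: ModelConstants = CONSTANTS,
    temp_mode: Literal["clamp", "strict"] = "clamp",
) -> dict[str, float]:
    """Methane-carbon releases: landfill CH4 not captured for use, and
    wetland CH4 (also reported by :func:`ecosystem_fluxes`)."""
    lin = _linear_temp_factor(forcings.temp, constants, temp_mode)
    return {
        "unused_ch4": pools.waste_ch4 * params.ch4_use_r,
        "wet_ch4_release": constants.wetland_ch4_frac * pools.wetland_c * lin,
    }


def compute_fluxes(
    pools: CarbonPools,
    profile: TouristProfile,
    forcings: Forcings,
    params: IslandParameters,
    constants: ModelConstants = CONSTANTS,
    temp_mode: Literal["clamp", "strict"] = "clamp",
) -> FluxSet:
    """Evaluate all 24 process fluxes for the current state."""
    values: dict[str, float] = {}
    values.update(tourism_fluxes(profile, forcings, params, constants))
    values.update(infrastructure_fluxes(profile, forcings, params, constants))
    values.update(ecosystem_fluxes(pools, forcings, params, constants, temp_mode))
    values.update(aquaculture_fluxes(forcings, params, constants))
    values.update(ch4_fluxes(pools, forcings, params, constants, temp_mode))
    return FluxSet(**values)
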