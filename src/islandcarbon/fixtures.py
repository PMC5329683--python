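"""Reference parameterizations of the Gouqi Island carbon-cycle model.

Three families of fixtures:

``as_printed``
    The source parameterization, transcribed value-for-value: visitor and
    resident counts, stay-day distribution, modal splits, per-unit emission
    coefficients and ecosystem rate constants for Gouqi Island (Zhoushan
    Archipelago, East China Sea), reference year 2014.  All initial stocks
    are zero, which makes every stock-proportional ecosystem flux
    identically zero — a degeneracy of the source parameterization that is
    preserved, not patched.

``calibrated``
    Starts from ``as_printed`` and applies a documented, minimal set of
    per-flux multipliers and positive initial stocks so that a one-year
    run reproduces the published 2014 budget table row-for-row at its
    printed nearest-10 precision.  The published coefficients are not
    unit-consistent with the published results (several rows differ from
    the raw computation by factors between 0.99 and ~20000), so the
    multipliers absorb those documented gaps; each override is listed with
    its derivation in the config's provenance block.  Construction fails
    loudly if any row misses its target.

``random_config(seed)``
    Seeded random variant for property tests: every positive quantity is
    scaled by an independent uniform factor in [0.5, 1.5], fractions are
    clipped to [0, 1] and the stay-day distribution renormalized, and
    initial stocks are drawn positive so stock-proportional fluxes are
    exercised.
"""

from __future__ import annotations

import numpy as np

from .budget import DEFAULT_MAPPING, aggregate, round_to_ten
from .config import ModelConfig
from .model import (
    CONSTANTS,
    CarbonPools,
    Forcings,
    IslandParameters,
    TouristProfile,
    aqu_area,
    compute_fluxes,
    forest_area,
    tidal_area,
)

__all__ = [
    "as_printed",
    "calibrated",
    "random_config",
    "get_fixture",
    "FIXTURE_NAMES",
    "CalibrationError",
    "REPORTED_BUDGET_2014",
    "REPORTED_TOTAL_EMISSION_2014",
    "REPORTED_TOTAL_SINK_2014",
    "REPORTED_CARBON_CREDIT_2014",
    "REPORTED_SAVING_ISLAND_TRANSPORT",
    "REPORTED_SAVING_FERRY",
]


class CalibrationError(RuntimeError):
    """The calibrated fixture failed to reproduce the published budget."""


#: published 2014 annual budget of Gouqi Island, tC/yr at nearest-10
#: precision: row name -> (column, value)
REPORTED_BUDGET_2014: dict[str, tuple[str, int]] = {
    "ferry": ("emission", 11070),
    "small_shuttle_bus": ("emission", 310),
    "private_car": ("emission", 1560),
    "fishing": ("emission", 1300),
    "visiting": ("emission", 320),
    "water_activity": ("emission", 1200),
    "shopping": ("emission", 270),
    "hotel": ("emission", 1220),
    "private_home": ("emission", 600),
    "desalination": ("emission", 6870),
    "mussel_aquaculture_activity": ("emission", 2100),
    "soil_respiration": ("emission", 6430),
    "solid_waste": ("emission", 700),
    "shell_aquaculture": ("sink", 41620),
    "forest_ecosystem": ("sink", 3750),
    "wetland_ecosystem": ("sink", 5870),
}

#: published headline totals for 2014 (the emission headline exceeds the
#: sum of the published emission rows by ~2830 tC/yr; the gap is reported,
#: not reconciled)
REPORTED_TOTAL_EMISSION_2014 = 36780.0
REPORTED_TOTAL_SINK_2014 = 51240.0
REPORTED_CARBON_CREDIT_2014 = -14460.0
#: published scenario savings (tC/yr)
REPORTED_SAVING_ISLAND_TRANSPORT = 1890.0
REPORTED_SAVING_FERRY = 12960.0


def as_printed() -> ModelConfig:
    """The source parameterization, transcribed verbatim."""
    return ModelConfig(
        name="as_printed",
        forcings=Forcings(
            temp=8.0,
            rade=1.2,
            nv=1_000_000.0,
            ni=10_000.0,
            land_area=6.62,
            inshore_area=1500.0,
        ),
        profile=TouristProfile(
            sd=(0.1, 0.2, 0.5, 0.1, 0.1),
            hotel_r=0.3,
            ph_r=0.7,
            moto_r=0.2,
            pc_r=0.1,
            ssd_r=0.7,
            pd_moto=6.0,
            pd_pc=20.0,
            pd_ssd=14.0,
        ),
        parameters=IslandParameters(
            w_growth_r=0.1,
            f_growth_r=0.1,
            w_re_r=0.2,
            f_re_r=0.2,
            dec_r=0.15,
            ads_r=0.1,
            forest_frac=0.53,
            tidal_frac=0.14,
            aqu_frac=0.005,
            growth_r=1_500_000.0,
            shell_c_r=0.95,
            ce_aqu=50_000.0,
            ce_car=5_400_000.0,
            ce_desalination=2784.0,
            ce_ferry=106.0,
            ce_fishing=1670.0,
            ce_hotel=7900.0,
            ce_moto=0.0,
            ce_pc=63.0,
            ce_ph=1619.0,
            ce_shopping=344.0,
            ce_ssb=40.0,
            ce_visiting=417.0,
            ce_wa=15_300.0,
            dis_ferry=140.0,
            per_wc=1.2,
            per_waste=1.1,
            pch4_waste=80_000.0,
            ch4_use_r=1.0,
            car_r=0.1,
        ),
        initial_stocks=CarbonPools(),
        provenance={
            "source": "transcribed 2014 Gouqi Island parameterization",
            "growth_r": "printed numeral kept verbatim; declared unit "
                        "mg C m-2 yr-1 (the only reading that puts the "
                        "shell sink on the published scale)",
        },
    )


def surveyed_visitors() -> ModelConfig:
    """``as_printed`` with the statistically reported visitor count.

    The equation parameterization uses 1,000,000 visitors/yr while the
    island statistics report 210,400 tourists; this variant selects the
    surveyed count.  The default stays at 1,000,000 because that value
    reproduces the published small-shuttle-bus row exactly.
    """
    base = as_printed()
    return base.with_updates(
        name="surveyed_visitors",
        forcings=base.forcings.model_copy(update={"nv": 210_400.0}).model_dump(),
    )


# targets of the person-driven (stock-independent) flux multipliers:
# flux name -> published row value.  ssb and shopping need no multiplier —
# the raw computation already matches the published rows at nearest-10.
_FLUX_TARGETS: dict[str, float] = {
    "ferry": 11070.0,
    "fishing": 1300.0,
    "visiting": 320.0,
    "wa": 1200.0,
    "hotel": 1220.0,
    "ph": 600.0,
    "desalination": 6870.0,
    "aquaculture": 2100.0,
    "waste": 700.0,
    "sg": 41620.0,
}
_PRIVATE_CAR_TARGET = 1560.0  # shared multiplier on pc + car

# net relative growth rates (1/yr) chosen for the calibrated ecosystems:
# round values giving stock magnitudes of a plausible order; the initial
# stock then follows from the published net annual row.
_KAPPA_WETLAND = 1.0
_KAPPA_FOREST = 2.0
_SOIL_TARGET = 6430.0
_WETLAND_TARGET = 5870.0
_FOREST_TARGET = 3750.0


def _annual_net_factor(kappa: float, dt: float) -> float:
    """Annual net growth of a stock under Euler stepping at rate kappa."""
    steps = round(1.0 / dt)
    return (1.0 + kappa * dt) ** steps - 1.0


def _soil_row(config: ModelConfig, soil_c: float) -> float:
    """Annual soil-respiration row for a candidate soil initial stock."""
    from .integrate import run  # local import to avoid a cycle at import time

    stocks = config.initial_stocks.model_copy(update={"soil_c": soil_c})
    probe = config.with_updates(initial_stocks=stocks.model_dump())
    table = aggregate(run(probe), DEFAULT_MAPPING)
    return table.row("soil_respiration").value


def calibrated() -> ModelConfig:
    """Fixture reproducing the published 2014 budget row-for-row.

    Raises :class:`CalibrationError` if any published row is missed at
    nearest-10 precision.
    """
    from .integrate import run

    base = as_printed()
    const = CONSTANTS
    f = base.forcings
    p = base.parameters

    # --- person-driven rows: exact ratio multipliers --------------------
    raw = compute_fluxes(CarbonPools(), base.profile, f, p, const).as_dict()
    multipliers = {name: target / raw[name] for name, target in _FLUX_TARGETS.items()}
    # the private-car row sums resident (pc) and tourist (car) cars; the
    # correction is carried entirely by the dominant resident-car term so
    # that every override stays individually necessary
    multipliers["pc"] = (_PRIVATE_CAR_TARGET - raw["car"]) / raw["pc"]

    # --- ecosystem rows: growth-rate override + initial stock -----------
    lin = const.ref_temp - f.temp
    q = const.q_base ** lin
    light = f.rade / (f.rade + const.light_half_sat) * const.light_scale
    t_area = tidal_area(p, f)
    f_area = forest_area(p, f)

    # wetland: loss rate per unit stock (respiration + litter + CH4)
    w_loss = (
        p.w_re_r * t_area * lin
        + const.litter_to_sea_frac
        + const.wetland_ch4_frac * lin
    )
    w_growth_cal = (w_loss + _KAPPA_WETLAND) / (t_area * q * light)
    wetland_c0 = _WETLAND_TARGET / _annual_net_factor(_KAPPA_WETLAND, base.dt)

    f_loss = p.f_re_r * f_area * lin + p.dec_r * lin
    f_growth_cal = (f_loss + _KAPPA_FOREST) / (f_area * q * light)
    forest_c0 = _FOREST_TARGET / _annual_net_factor(_KAPPA_FOREST, base.dt)

    cfg = base.with_parameter_overrides(
        w_growth_r=w_growth_cal, f_growth_r=f_growth_cal
    ).with_updates(
        name="calibrated",
        flux_multipliers=multipliers,
        initial_stocks=CarbonPools(
            forest_c=forest_c0, wetland_c=wetland_c0
        ).model_dump(),
    )

    # soil: the soil-respiration row is linear in the soil initial stock
    # (with a fixed contribution from forest litter decomposition); solve
    # by two probe runs.
    a0 = _soil_row(cfg, 0.0)
    a1 = _soil_row(cfg, 1.0)
    soil_c0 = (_SOIL_TARGET - a0) / (a1 - a0)
    if soil_c0 <= 0:
        raise CalibrationError(
            f"soil calibration needs a non-positive initial stock ({soil_c0})"
        )
    cfg = cfg.with_updates(
        initial_stocks=CarbonPools(
            forest_c=forest_c0, wetland_c=wetland_c0, soil_c=soil_c0
        ).model_dump(),
        provenance={
            **base.provenance,
            "calibration": (
                "per-flux multipliers = published row / raw computed flux "
                "(ferry, fishing, visiting, wa, hotel, ph, desalination, "
                "aquaculture, waste, sg; the private-car correction rides "
                "on pc alone, car stays as transcribed); "
                "ssb and shopping need none. Ecosystem rows: growth rates "
                f"rescaled so net relative growth is {_KAPPA_WETLAND}/yr "
                f"(wetland) and {_KAPPA_FOREST}/yr (forest), initial stocks "
                "then fixed by the published net rows under 12-step Euler; "
                "soil initial stock solved linearly from the published "
                "soil-respiration row."
            ),
        },
    )

    # --- verify every published row at nearest-10 precision -------------
    table = aggregate(run(cfg), DEFAULT_MAPPING)
    residuals = {}
    for name, (column, target) in REPORTED_BUDGET_2014.items():
        row = table.row(name)
        got = round_to_ten(row.value)
        if row.column != column or got != target:
            residuals[name] = (got, target)
    if residuals:
        raise CalibrationError(
            f"calibration missed published rows (got, target): {residuals}"
        )
    return cfg


def random_config(seed: int) -> ModelConfig:
    """Seeded random parameterization for property tests.

    Multiplies every positive scalar of the ``as_printed`` fixture by an
    independent uniform factor in [0.5, 1.5] (fractions clipped to [0, 1],
    stay-day distribution renormalized) and draws positive initial stocks
    so that stock-proportional fluxes are non-trivial.  Reproducible from
    the seed alone.
    """
    rng = np.random.default_rng(seed)
    base = as_printed()

    def jitter(x: float) -> float:
        return float(x * rng.uniform(0.5, 1.5))

    def jitter_frac(x: float) -> float:
        return float(np.clip(x * rng.uniform(0.5, 1.5), 0.0, 1.0))

    sd = np.array([jitter(x) for x in base.profile.sd])
    sd = tuple(float(v) for v in sd / sd.sum())
    profile = TouristProfile(
        sd=sd,
        hotel_r=jitter_frac(base.profile.hotel_r),
        ph_r=jitter_frac(base.profile.ph_r),
        moto_r=jitter_frac(base.profile.moto_r),
        pc_r=jitter_frac(base.profile.pc_r),
        ssd_r=jitter_frac(base.profile.ssd_r),
        pd_moto=jitter(base.profile.pd_moto),
        pd_pc=jitter(base.profile.pd_pc),
        pd_ssd=jitter(base.profile.pd_ssd),
    )
    forcings = Forcings(
        temp=jitter(base.forcings.temp),
        rade=jitter(base.forcings.rade),
        nv=jitter(base.forcings.nv),
        ni=jitter(base.forcings.ni),
        land_area=jitter(base.forcings.land_area),
        inshore_area=jitter(base.forcings.inshore_area),
    )
    pdata = {}
    for name, value in base.parameters.model_dump().items():
        if name in ("forest_frac", "tidal_frac", "aqu_frac", "shell_c_r",
                    "ch4_use_r", "car_r"):
            pdata[name] = jitter_frac(value)
        else:
            pdata[name] = jitter(value)
    stocks = CarbonPools(
        forest_c=float(rng.uniform(0.0, 5000.0)),
        wetland_c=float(rng.uniform(0.0, 5000.0)),
        shell_c=float(rng.uniform(0.0, 5000.0)),
        soil_c=float(rng.uniform(0.0, 5000.0)),
        waste_ch4=float(rng.uniform(0.0, 5000.0)),
        total_ch4=float(rng.uniform(0.0, 5000.0)),
    )
    return ModelConfig(
        name=f"random_{seed}",
        parameters=IslandParameters(**pdata),
        forcings=forcings,
        profile=profile,
        initial_stocks=stocks,
        provenance={"seed": str(seed)},
    )


def packaged_config(name: str) -> ModelConfig:
    """Load one of the fixture config files shipped with the package."""
    from importlib import resources

    from .config import config_from_dict
    import yaml

    path = resources.files("islandcarbon") / "data" / f"{name}.yaml"
    try:
        text = path.read_text()
    except FileNotFoundError:
        raise KeyError(f"no packaged config named {name!r}") from None
    return config_from_dict(yaml.safe_load(text))


FIXTURE_NAMES = ("as_printed", "calibrated", "surveyed_visitors", "random")


def get_fixture(name: str, seed: int | None = None) -> ModelConfig:
    """Look up a fixture by name (``random`` requires a seed)."""
    if name == "as_printed":
        return as_printed()
    if name == "calibrated":
        return calibrated()
    if name == "surveyed_visitors":
        return surveyed_visitors()
    if name == "random":
        if seed is None:
            raise ValueError("the random fixture requires a seed")
        return random_config(seed)
    raise KeyError(
        f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}"
    )
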