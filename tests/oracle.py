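"""Independent single-expression oracle for the 24 process fluxes.

Each flux is transcribed here as one flat arithmetic expression over plain
numbers, with the unit conversions written out literally (1e-6 t/g,
12/44 gCO2->gC, 12/16 gCH4->gC, 1e-3 g/mg, 1e6 m2/km2).  Nothing from
``islandcarbon.model`` is used, so the expressions stay an independent
check on the flux implementation.
"""

from __future__ import annotations


def oracle_fluxes(config, pools=None) -> dict[str, float]:
    """Expected fluxes for a config (and optional pool state), in tC/yr."""
    p = config.parameters.model_dump()
    f = config.forcings.model_dump()
    t = config.profile.model_dump()
    s = (pools or config.initial_stocks).model_dump()

    NV, NI = f["nv"], f["ni"]
    SD1, SD2, SD3, SD4, SD5 = (x * NV for x in t["sd"])
    ACT = 1 * SD1 + 2 * SD2 + 3 * SD3 + 4 * SD4 + 5 * SD5
    NIGHTS = 0 * SD1 + 1 * SD2 + 2 * SD3 + 3 * SD4 + 4 * SD5
    TIDAL_AREA = p["tidal_frac"] * f["land_area"]
    FOREST_AREA = p["forest_frac"] * f["land_area"]
    AQU_AREA = p["aqu_frac"] * f["inshore_area"]
    temp, rade = f["temp"], f["rade"]
    assert temp < 20.0, "oracle transcribes the sub-reference-temperature regime"
    CO2 = 1e-6 * 12 / 44  # g CO2 -> tC
    CH4 = 1e-6 * 12 / 16  # g CH4 -> tC

    return {
        "w_res": p["w_re_r"] * TIDAL_AREA * (20 - temp) * s["wetland_c"],
        "f_res": s["forest_c"] * FOREST_AREA * p["f_re_r"] * (20 - temp),
        "aquaculture": AQU_AREA * p["ce_aqu"] * CO2,
        "pc": p["car_r"] * NI * p["ce_car"] * CO2,
        "desalination": (ACT + 365 * NI) * p["per_wc"] * p["ce_desalination"] * CO2,
        "shopping": ACT * p["ce_shopping"] * CO2,
        "wa": ACT * p["ce_wa"] * CO2,
        "visiting": ACT * p["ce_visiting"] * CO2,
        "fishing": ACT * p["ce_fishing"] * CO2,
        "hotel": NIGHTS * t["hotel_r"] * p["ce_hotel"] * CO2,
        "ph": NIGHTS * p["ce_ph"] * t["ph_r"] * CO2,
        "ferry": NV * p["dis_ferry"] * p["ce_ferry"] * CO2,
        "rm": ACT * t["moto_r"] * t["pd_moto"] * p["ce_moto"] * CO2,
        "car": ACT * t["pd_pc"] * t["pc_r"] * p["ce_pc"] * CO2,
        "ssb": ACT * t["pd_ssd"] * t["ssd_r"] * p["ce_ssb"] * CO2,
        "w_pho": s["wetland_c"] * p["w_growth_r"] * TIDAL_AREA
        * 1.05 ** (20 - temp) * (rade / (rade + 6) * 690),
        "f_pho": s["forest_c"] * p["f_growth_r"] * FOREST_AREA
        * 1.05 ** (20 - temp) * (rade / (rade + 6) * 690),
        "adsorption": s["soil_c"] * p["ads_r"] * (20 - temp),
        "sg": AQU_AREA * 1e6 * (p["growth_r"] * 1e-3) * p["shell_c_r"] / 0.27 * 1e-6,
        "decomposition": s["forest_c"] * p["dec_r"] * (20 - temp),
        "wet_ch4_release": 0.1 * s["wetland_c"] * (20 - temp),
        "unused_ch4": s["waste_ch4"] * p["ch4_use_r"],
        "waste": (ACT + 365 * NI) * p["per_waste"] * p["pch4_waste"] * CH4,
        "litter_to_sea": 0.5 * s["wetland_c"],
    }


def oracle_cumsum(initial: dict[str, float], flux_sets, dt: float) -> dict[str, float]:
    """Independent cumulative-sum transcription of the stock-update rule."""
    s = dict(initial)
    for f in flux_sets:
        s["co2_exchange"] += (
            f["w_res"] + f["f_res"] + f["aquaculture"] + f["pc"]
            + f["desalination"] + f["shopping"] + f["wa"] + f["visiting"]
            + f["fishing"] + f["hotel"] + f["ph"] + f["ferry"] + f["rm"]
            + f["car"] + f["ssb"]
            - f["w_pho"] - f["f_pho"] - f["adsorption"] - f["sg"]
        ) * dt
        s["forest_c"] += (f["f_pho"] - f["f_res"] - f["decomposition"]) * dt
        s["wetland_c"] += (
            f["w_pho"] - f["w_res"] - f["litter_to_sea"] - f["wet_ch4_release"]
        ) * dt
        s["shell_c"] += f["sg"] * dt
        s["soil_c"] += (f["adsorption"] + f["decomposition"]) * dt
        s["waste_ch4"] += (f["waste"] - f["unused_ch4"]) * dt
        s["total_ch4"] += (f["wet_ch4_release"] + f["unused_ch4"]) * dt
    return s
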