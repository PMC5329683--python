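# as_printed fixture: the 2014 Gouqi Island parameterization transcribed
# value-for-value from the source model listing.  Initial stocks are zero
# (the listing's INIT values), which leaves every stock-proportional
# ecosystem flux identically zero.
# Provenance notes are embedded in the `provenance` mapping below.
added_sinks: []
constants:
  ch4_to_c: 0.75
  co2_to_c: 0.2727272727272727
  days_per_year: 365.0
  light_half_sat: 6.0
  light_scale: 690.0
  litter_to_sea_frac: 0.5
  q_base: 1.05
  ref_temp: 20.0
  shell_carbon_divisor: 0.27
  wetland_ch4_frac: 0.1
dt: 0.08333333333333333
extra_emissions: {}
flux_multipliers: {}
forcings:
  inshore_area: 1500.0
  land_area: 6.62
  ni: 10000.0
  nv: 1000000.0
  rade: 1.2
  temp: 8.0
horizon: 1.0
initial_stocks:
  co2_exchange: 0.0
  forest_c: 0.0
  shell_c: 0.0
  soil_c: 0.0
  total_ch4: 0.0
  waste_ch4: 0.0
  wetland_c: 0.0
name: as_printed
negative_stock: floor
parameters:
  ads_r: 0.1
  aqu_frac: 0.005
  car_r: 0.1
  ce_aqu: 50000.0
  ce_car: 5400000.0
  ce_desalination: 2784.0
  ce_ferry: 106.0
  ce_fishing: 1670.0
  ce_hotel: 7900.0
  ce_moto: 0.0
  ce_pc: 63.0
  ce_ph: 1619.0
  ce_shopping: 344.0
  ce_ssb: 40.0
  ce_visiting: 417.0
  ce_wa: 15300.0
  ch4_use_r: 1.0
  dec_r: 0.15
  dis_ferry: 140.0
  f_growth_r: 0.1
  f_re_r: 0.2
  forest_frac: 0.53
  growth_r: 1500000.0
  pch4_waste: 80000.0
  per_waste: 1.1
  per_wc: 1.2
  shell_c_r: 0.95
  tidal_frac: 0.14
  w_growth_r: 0.1
  w_re_r: 0.2
profile:
  hotel_r: 0.3
  moto_r: 0.2
  pc_r: 0.1
  pd_moto: 6.0
  pd_pc: 20.0
  pd_ssd: 14.0
  ph_r: 0.7
  sd:
  - 0.1
  - 0.2
  - 0.5
  - 0.1
  - 0.1
  ssd_r: 0.7
provenance:
  growth_r: printed numeral kept verbatim; declared unit mg C m-2 yr-1 (the only reading
    that puts the shell sink on the published scale)
  source: transcribed 2014 Gouqi Island parameterization
temp_mode: clamp
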