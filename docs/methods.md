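# Methods

## Model structure

The simulator is a compartment (stock-and-flow) model of an island
social–ecological system. State is seven carbon stocks in tonnes of carbon
(tC): a cumulative atmospheric-exchange accumulator `co2_exchange` (net
carbon released to the atmosphere as CO₂; any sign), forest biomass
`forest_c`, wetland plant `wetland_c`, mussel-shell carbonate `shell_c`,
soil `soil_c`, landfill methane `waste_ch4` and cumulative released methane
`total_ch4` (all ≥ 0). Twenty-four named process fluxes (tC yr⁻¹,
non-negative by construction; direction is carried by the stock-update rule
and by emission/sink/internal role tags) connect the stocks and the outside
world. Forcings — temperature, solar radiation, visitor and resident
counts, land and inshore areas — are constant within a run: the model
targets one representative year, not multi-year dynamics.

Updating is explicit fixed-step (Euler): fluxes are evaluated from the
state at the start of each step and stocks advance by
(inflows − outflows)·dt. This mirrors the difference-equation semantics of
visual stock-and-flow modelling environments; the difference equations,
not their continuum limit, are the specified model, so no adaptive solver
is used. Default dt = 1/12 yr over a 1-yr horizon (12 steps). Halving dt
leaves person-driven annual totals unchanged (they are constant in time)
and changes stock-proportional totals at first order in dt, both
property-tested.

## Units and conversions

The canonical internal unit is tC for stocks and tC yr⁻¹ for fluxes.
Per-unit emission coefficients keep their reported unit — grams of CO₂ (or
CH₄) per km, per night, per tonne of desalinated water, per visitor-day —
and are converted exactly once, at the flux boundary, by the molar-mass
ratios 12/44 (CO₂→C) and 12/16 (CH₄→C). Each coefficient's unit is declared
in the config schema (`CANONICAL_UNITS`); a config file may restate a unit,
and a restated unit must match the canonical one exactly — units are
validated, never guessed.

Two declared-unit decisions deserve note, because the transcribed
coefficient table is not internally unit-consistent:

* **Mussel growth `growth_r`.** The transcribed numeral is 1,500,000 with a
  nominal unit of g C m⁻² yr⁻¹, which is physically absurd (1.5 t C per m²)
  and puts the shell sink three orders of magnitude off its published scale.
  The package keeps the numeral verbatim and declares the unit
  **mg C m⁻² yr⁻¹** (= 1500 g C m⁻² yr⁻¹, a realistic areal mussel growth),
  the only reading that lands the shell-growth flux
  `area·growth·shell_c_r/0.27` on the published order (≈3.96×10⁴ tC yr⁻¹
  before calibration, vs 41,620 published).
* **Aquaculture activity `ce_aqu`.** Kept at its reported per-km² reading
  even though the resulting flux (≈0.1 tC yr⁻¹) is ~4 orders below the
  published row; no unit reinterpretation is uniquely defensible, so the
  gap is closed by an explicit calibration multiplier instead of a guess.

The divisor 0.27 in the shell flux is exposed as the named constant
`shell_carbon_divisor` without further interpretation (plausibly the carbon
mass fraction of shell material in the carbonate stoichiometry
Ca²⁺ + 2HCO₃⁻ → CaCO₃ + CO₂ + H₂O).

## Temperature and light responses

Photosynthesis uses `q_base^(ref_temp − T)` with q_base = 1.05 and
ref_temp = 20 °C, times the saturating light factor
`R/(R + K)·S` with half-saturation K = 6 MJ m⁻² yr⁻¹ and scale S = 690.
The parenthesization is fixed as Michaelis–Menten: `(R/(R+K))·S`.
Respiration, decomposition and soil uptake use the linear factor
`(ref_temp − T)`. The model is exercised at T = 8 °C; for T ≥ 20 °C the
linear factor would go negative, so it is clamped at zero with a logged
warning by default, and a strict mode raises a domain error instead.

## Budget accounting

One simulated year aggregates into a two-column table via an explicit,
total flux-to-row mapping: every flux belongs to exactly one row (possibly
summed or netted) or is declared internal; an unmapped flux is a
configuration error, never silently dropped. Conventions of the default
mapping:

* private car row = resident cars (`pc`) + tourist cars (`car`); rental
  motorcycles keep a separate row (zero under the transcribed zero per-km
  coefficient);
* ecosystem rows are net annual fluxes: forest = photosynthesis −
  respiration − litter decomposition; wetland = photosynthesis −
  respiration − CH₄ release − litter export to sea;
* the soil-respiration row carries the magnitude of the soil-uptake
  pathway but is classified as an **emission**, matching the reference
  budget's published layout even though the stock equations treat the same
  flux as a capture; the classification is data in the mapping, not code;
* the landfill-CH₄ reuse transfer is internal.

Carbon credit = total emission − total sink (negative = net removal).
Shares are row / column total × 100, reported to 0.1 % (half-up); table
values render at the nearest 10 tC yr⁻¹ (half-up), the published precision.
The published emission headline (36,780 tC yr⁻¹) exceeds the sum of the
published emission rows (33,950) by ~2,830 tC yr⁻¹; the package always
reports its own row sum and offers an optional *headline emission* override
used solely as the denominator of shares and reduction percentages, so both
readings are available and the gap stays visible.

Mass conservation holds exactly in the Euler arithmetic: the change of
total stored carbon over a run equals the integrated boundary fluxes
(person-driven emissions and landfill CH₄ in, wetland litter export out);
this is property-tested to 1e-9 relative to the gross balance-sheet
magnitude. Flooring a stock at zero after an overdraw (possible under
aggressive random parameterizations, since explicit stepping can overshoot
a linear outflow when rate·dt > 1) breaks the identity by construction and
is excluded from that test; a strict mode turns overdraws into errors.

## Fixtures and calibration

`as_printed` transcribes the source parameterization value-for-value,
including its zero initial stocks, which leave every stock-proportional
ecosystem flux identically zero — a degeneracy that is preserved and
tested, not patched. Non-degenerate runs need positive initial stocks,
which only the calibrated fixture supplies.

`calibrated` reproduces the published 2014 budget row-for-row at nearest-10
precision using the smallest override set we could make individually
necessary (a leave-one-out test asserts each one breaks a row when
reverted):

* **Person-driven rows** get exact ratio multipliers, published row ÷ raw
  computed flux, applied to the flux output (ferry 2.735, fishing 0.984,
  visiting 0.970, water activity 0.099, hotel 0.993, private home 1.022,
  desalination 1.151, aquaculture ≈2.05×10⁴, solid waste ≈1.6×10⁻³, shell
  growth 1.051). The shuttle-bus and shopping rows need none — the raw
  computation already matches at nearest-10, which is also the package's
  strongest evidence that the transcription is faithful. The private-car
  correction rides on the resident-car flux alone (tourist cars stay as
  transcribed), keeping each override necessary.
* **Ecosystem rows** are under-determined (one published net row, several
  unknown stocks and rates per ecosystem). The convention adopted: rescale
  the growth rate so the net relative growth rate is a round value —
  1 yr⁻¹ (wetland) and 2 yr⁻¹ (forest), chosen to give stock magnitudes of
  a plausible order (W₀ ≈ 3,639 tC, F₀ ≈ 700 tC) and to keep the soil
  solution positive — then fix the initial stock from the published net
  row under 12-step Euler growth, `stock₀ = row / ((1 + κ/12)¹² − 1)`.
  The soil initial stock (≈2,214 tC) is solved linearly from the published
  soil-respiration row after accounting for the decomposition inflow from
  the forest.

`calibrated()` recomputes all of this from scratch at construction and
fails loudly if any published row is missed; the shipped
`data/calibrated.yaml` mirrors the computed values and is cross-checked in
tests.

`random_config(seed)` multiplies every positive scalar by an independent
uniform factor in [0.5, 1.5] (fractions clipped to [0, 1], stay-day
distribution renormalized) and draws initial stocks uniformly in
[0, 5000] tC so stock-proportional fluxes are exercised; it is reproducible
from the seed alone.

### What the synthetic variants do and do not show

The random configs probe algebraic structure — oracle equivalence,
linearity, non-negativity, conservation, scenario monotonicity — under wide
parameter variation. They do not emulate covariance between real
parameters (e.g. visitor numbers and lodging shares move together in
reality), sub-annual seasonality (forcings are annual means), or
demographic/tourism growth across years; passing them validates the
implementation of the stated model, not the model's fidelity to the real
island.

## Scenarios

Scenario transforms are pure functions on the immutable config:
`electrify_island_transport` zeroes the four road-transport coefficients;
`electrify_ferry` zeroes the ferry coefficient; `add_macroalgae_sink`
appends a constant-rate sink row (default 3,350 tC yr⁻¹ km⁻², area a
multiple of the mussel-culture area) to the budget without entering the
stock dynamics. Comparison reports per-row and total savings, the
percentage reduction of total emission (against the model's own total or
the headline override) and the change in carbon credit. Electrification
can only remove emissions, so total emission is monotonically
non-increasing under it — property-tested.

Model-computed savings differ from the published scenario headlines (1,870
vs 1,890 tC yr⁻¹ for road transport; 11,070 vs 12,960 for the ferry,
where the published saving also disagrees with the published ferry row);
the published figures ship as reference constants so both can be reported.

## Numerical choices and limitations

* Problem sizes: every shipped computation is a 12-step scalar run;
  the full test suite and the reproduction script complete in seconds.
* Rounding: nearest-10 (half-up) for table values, 0.1 % (half-up) for
  shares, via decimal arithmetic to avoid binary-float ties.
* Degenerate inputs: zero visitors/residents zero all person fluxes; zero
  stocks zero all stock-proportional fluxes; zero column totals make
  shares an explicit error rather than NaN.
* Determinism: identical config (and seed, where randomness exists) gives
  bitwise-identical trajectories; run logs record a SHA-256 config hash.
* CH₄ is tracked as carbon mass only; no CO₂-equivalent (GWP) weighting.
* No spatial structure, no inbound/outbound tourist transport beyond the
  ferry, no economic analysis.
* The calibrated ecosystem stocks are a reporting convention, not an
  estimate of the island's actual biomass: the published net rows cannot
  identify stocks and rates separately.
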