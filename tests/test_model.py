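"""Unit tests of the domain types and the 24 process fluxes."""

import math

import pytest
from hypothesis import given, settings, strategies as st
from pydantic import ValidationError

from islandcarbon import (
    CONSTANTS,
    CarbonPools,
    DomainError,
    FluxError,
    FluxSet,
    FLUX_NAMES,
    FLUX_ROLES,
    Forcings,
    TouristProfile,
    aquaculture_fluxes,
    ch4_fluxes,
    compute_fluxes,
    ecosystem_fluxes,
    g_co2_to_tc,
    infrastructure_fluxes,
    lodging_nights,
    tc_to_g_co2,
    tourism_fluxes,
    visitor_activity_days,
)
from islandcarbon.fixtures import random_config

from oracle import oracle_fluxes


def profile(sd=(0.1, 0.2, 0.5, 0.1, 0.1), **kw):
    base = dict(hotel_r=0.3, ph_r=0.7, moto_r=0.2, pc_r=0.1, ssd_r=0.7,
                pd_moto=6.0, pd_pc=20.0, pd_ssd=14.0)
    base.update(kw)
    return TouristProfile(sd=sd, **base)


class TestPersonDayWeights:
    def test_activity_days_printed_distribution(self):
        # 1*0.1 + 2*0.2 + 3*0.5 + 4*0.1 + 5*0.1 = 2.9 days per visitor
        assert visitor_activity_days(profile(), 1_000_000) == pytest.approx(2_900_000)

    def test_lodging_nights_printed_distribution(self):
        # (k-1)-weighted sum = 1.9 nights per visitor
        assert lodging_nights(profile(), 1_000_000) == pytest.approx(1_900_000)

    def test_zero_visitors(self):
        assert visitor_activity_days(profile(), 0) == 0
        assert lodging_nights(profile(), 0) == 0

    def test_day_trippers(self):
        p = profile(sd=(1.0, 0.0, 0.0, 0.0, 0.0))
        assert visitor_activity_days(p, 12345) == pytest.approx(12345)
        assert lodging_nights(p, 98765) == 0

    def test_negative_visitors_rejected(self):
        with pytest.raises(DomainError):
            visitor_activity_days(profile(), -1)

    @pytest.mark.parametrize("sd", [
        (0.1, 0.2, 0.5, 0.1, 0.2),   # sums to 1.1
        (0.5, 0.5, 0.5, -0.5, 0.0),  # negative fraction
        (1.2, -0.2, 0.0, 0.0, 0.0),  # outside [0,1]
    ])
    def test_invalid_stay_distribution_rejected(self, sd):
        with pytest.raises(ValidationError):
            profile(sd=sd)

    @given(st.integers(0, 10**7),
           st.lists(st.floats(0.01, 1.0), min_size=5, max_size=5))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_activity_days_bounds_and_night_identity(self, nv, weights):
        total = sum(weights)
        p = profile(sd=tuple(w / total for w in weights))
        days = visitor_activity_days(p, nv)
        assert nv * 1 - 1e-6 * nv <= days <= nv * 5 + 1e-6 * nv
        # every stay contributes exactly one more day than nights
        assert lodging_nights(p, nv) == pytest.approx(days - nv, abs=1e-6 * max(nv, 1))


class TestTourismFluxes:
    def test_shuttle_bus_matches_published_row(self, as_printed_config):
        c = as_printed_config
        out = tourism_fluxes(c.profile, c.forcings, c.parameters)
        # 2.9e6 person-days * 14 km/day * 0.7 modal share * 40 g CO2/km
        assert round(out["ssb"] / 10) * 10 == 310

    def test_zero_coefficient_zeroes_rentals(self, as_printed_config):
        c = as_printed_config
        out = tourism_fluxes(c.profile, c.forcings, c.parameters)
        assert out["rm"] == 0.0

    def test_scaling_single_coefficient_is_isolated(self, as_printed_config):
        c = as_printed_config
        base = tourism_fluxes(c.profile, c.forcings, c.parameters)
        bumped = tourism_fluxes(
            c.profile, c.forcings,
            c.parameters.model_copy(update={"ce_hotel": c.parameters.ce_hotel * 3}),
        )
        assert bumped["hotel"] == pytest.approx(3 * base["hotel"], rel=1e-12)
        for k in base:
            if k != "hotel":
                assert bumped[k] == base[k]


class TestInfrastructureFluxes:
    def test_empty_island_has_no_infrastructure_load(self, as_printed_config):
        c = as_printed_config
        f = c.forcings.model_copy(update={"nv": 0.0, "ni": 0.0})
        out = infrastructure_fluxes(c.profile, f, c.parameters)
        assert all(v == 0.0 for v in out.values())

    def test_desalination_from_printed_parameters(self, as_printed_config):
        c = as_printed_config
        out = infrastructure_fluxes(c.profile, c.forcings, c.parameters)
        # (2.9e6 visitor-days + 3.65e6 resident-days) * 1.2 t * 2784 g CO2/t
        assert out["desalination"] == pytest.approx(5967.88, abs=0.01)

    def test_ferry_linear_in_visitors(self, as_printed_config):
        c = as_printed_config
        base = infrastructure_fluxes(c.profile, c.forcings, c.parameters)
        doubled = infrastructure_fluxes(
            c.profile,
            c.forcings.model_copy(update={"nv": 2 * c.forcings.nv}),
            c.parameters,
        )
        assert doubled["ferry"] == pytest.approx(2 * base["ferry"], rel=1e-12)
        assert doubled["pc"] == base["pc"]  # resident cars independent of tourists


class TestEcosystemFluxes:
    def test_zero_stocks_zero_fluxes(self, as_printed_config):
        c = as_printed_config
        out = ecosystem_fluxes(CarbonPools(), c.forcings, c.parameters)
        assert all(v == 0.0 for v in out.values())

    def test_reference_temperature_kills_linear_terms(self, as_printed_config):
        c = as_printed_config
        pools = CarbonPools(forest_c=100, wetland_c=100, soil_c=100)
        out = ecosystem_fluxes(
            pools, c.forcings.model_copy(update={"temp": 20.0}), c.parameters
        )
        for name in ("w_res", "f_res", "adsorption", "decomposition",
                     "wet_ch4_release"):
            assert out[name] == 0.0
        # the exponential factor is q**0 = 1, photosynthesis persists
        assert out["w_pho"] > 0 and out["f_pho"] > 0

    def test_wetland_photosynthesis_printed_expression(self, as_printed_config):
        c = as_printed_config
        pools = CarbonPools(wetland_c=100.0)
        out = ecosystem_fluxes(pools, c.forcings, c.parameters)
        expected = 100 * 0.1 * 0.9268 * 1.05**12 * (1.2 / 7.2 * 690)
        assert out["w_pho"] == pytest.approx(expected, rel=1e-9)

    def test_above_reference_temperature_clamps_or_raises(self, as_printed_config):
        c = as_printed_config
        hot = c.forcings.model_copy(update={"temp": 25.0})
        pools = CarbonPools(forest_c=10, wetland_c=10, soil_c=10)
        out = ecosystem_fluxes(pools, hot, c.parameters, temp_mode="clamp")
        assert out["f_res"] == 0.0 and out["adsorption"] == 0.0
        with pytest.raises(DomainError):
            ecosystem_fluxes(pools, hot, c.parameters, temp_mode="strict")


class TestAquacultureFluxes:
    def test_no_culture_area_no_fluxes(self, as_printed_config):
        c = as_printed_config
        p = c.parameters.model_copy(update={"aqu_frac": 0.0})
        out = aquaculture_fluxes(c.forcings, p)
        assert out == {"aquaculture": 0.0, "sg": 0.0}

    def test_shell_sink_magnitude(self, as_printed_config):
        c = as_printed_config
        out = aquaculture_fluxes(c.forcings, c.parameters)
        # 7.5 km2 culture, 1500 g C m-2 yr-1 growth, 0.95 shell carbon,
        # 0.27 carbonate divisor -> ~3.96e4 tC/yr
        assert out["sg"] == pytest.approx(39583.33, abs=0.01)

    def test_linear_in_area(self, as_printed_config):
        c = as_printed_config
        base = aquaculture_fluxes(c.forcings, c.parameters)
        doubled = aquaculture_fluxes(
            c.forcings,
            c.parameters.model_copy(update={"aqu_frac": 2 * c.parameters.aqu_frac}),
        )
        for k in base:
            assert doubled[k] == pytest.approx(2 * base[k], rel=1e-12)


class TestCh4Fluxes:
    def test_zero_pools(self, as_printed_config):
        c = as_printed_config
        out = ch4_fluxes(CarbonPools(), c.forcings, c.parameters)
        assert out == {"unused_ch4": 0.0, "wet_ch4_release": 0.0}

    def test_full_use_rate_drains_pool_rate(self, as_printed_config):
        c = as_printed_config
        out = ch4_fluxes(CarbonPools(waste_ch4=50.0), c.forcings, c.parameters)
        assert out["unused_ch4"] == pytest.approx(50.0)

    def test_zero_use_rate(self, as_printed_config):
        c = as_printed_config
        p = c.parameters.model_copy(update={"ch4_use_r": 0.0})
        out = ch4_fluxes(CarbonPools(waste_ch4=50.0), c.forcings, p)
        assert out["unused_ch4"] == 0.0


class TestFluxSetInvariants:
    def test_roles_are_total(self):
        assert set(FLUX_ROLES) == set(FLUX_NAMES)
        assert set(FLUX_ROLES.values()) == {"emission", "sink", "internal"}

    def test_negative_flux_rejected_by_name(self):
        with pytest.raises(FluxError, match="ferry"):
            FluxSet(ferry=-1.0)

    def test_non_finite_flux_rejected_by_name(self):
        with pytest.raises(FluxError, match="sg"):
            FluxSet(sg=math.inf)

    @pytest.mark.parametrize("seed", range(10))
    def test_all_fluxes_non_negative_for_random_configs(self, seed):
        cfg = random_config(seed)
        fs = compute_fluxes(cfg.initial_stocks, cfg.profile, cfg.forcings,
                            cfg.parameters)
        assert all(v >= 0.0 for v in fs.as_dict().values())

    def test_visitor_scaling_touches_exactly_the_visitor_fluxes(self):
        cfg = random_config(7)
        args = (cfg.profile, cfg.parameters)
        base = compute_fluxes(cfg.initial_stocks, cfg.profile, cfg.forcings,
                              cfg.parameters).as_dict()
        lam = 3.0
        scaled = compute_fluxes(
            cfg.initial_stocks, cfg.profile,
            cfg.forcings.model_copy(update={"nv": lam * cfg.forcings.nv}),
            cfg.parameters,
        ).as_dict()
        visitor_linear = {"shopping", "wa", "visiting", "fishing", "hotel",
                          "ph", "rm", "car", "ssb", "ferry"}
        for name in visitor_linear:
            assert scaled[name] == pytest.approx(lam * base[name], rel=1e-12)
        # mixed person-day fluxes grow, but less than lambda-fold
        for name in ("desalination", "waste"):
            assert base[name] < scaled[name] < lam * base[name]
        for name in set(base) - visitor_linear - {"desalination", "waste"}:
            assert scaled[name] == base[name]


class TestUnitConversions:
    @given(st.floats(1e-6, 1e9))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_tc_g_co2_round_trip(self, x):
        assert tc_to_g_co2(g_co2_to_tc(x)) == pytest.approx(x, rel=1e-12)
        assert g_co2_to_tc(tc_to_g_co2(x)) == pytest.approx(x, rel=1e-12)

    def test_molar_ratios(self):
        assert CONSTANTS.co2_to_c == pytest.approx(12 / 44)
        assert CONSTANTS.ch4_to_c == pytest.approx(12 / 16)


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(100))
    def test_every_flux_matches_flat_transcription(self, seed):
        """Each computed flux equals an independently coded one-line
        transcription of its process equation, over seeded random
        parameterizations."""
        cfg = random_config(seed)
        ours = compute_fluxes(cfg.initial_stocks, cfg.profile, cfg.forcings,
                              cfg.parameters).as_dict()
        expected = oracle_fluxes(cfg)
        assert set(ours) == set(expected)
        for name in ours:
            assert ours[name] == pytest.approx(expected[name], rel=1e-9), name
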