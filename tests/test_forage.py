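"""Forage production stage: water bucket, growth, nitrogen, spin-up."""

import dataclasses
import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rangeland.forage import (
    ClimateSeries,
    ForageState,
    GrassParams,
    SoilProfile,
    apply_offtake,
    bucket_capacity,
    crude_protein,
    live_digestibility,
    spin_up,
    step_growth,
    water_balance,
)

SANDY = SoilProfile(sand_fraction=0.6, silt_fraction=0.25, clay_fraction=0.15)
CLAY = SoilProfile(sand_fraction=0.2, silt_fraction=0.3, clay_fraction=0.5)
PARAMS = GrassParams()


def one_year_climatology(precip_mm, temp=22.0, start_year=2000):
    monthly = precip_mm / 12.0
    return ClimateSeries(
        months=tuple((start_year, m) for m in range(1, 13)),
        precip=tuple([monthly] * 12),
        temp_mean=tuple([temp] * 12),
    )


class TestSoilProfile:
    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            SoilProfile(sand_fraction=0.5, silt_fraction=0.6,
                        clay_fraction=0.2)

    def test_negative_fraction_rejected(self):
        with pytest.raises(ValueError):
            SoilProfile(sand_fraction=-0.1, silt_fraction=0.6,
                        clay_fraction=0.5)

    def test_capacity_ordered_by_texture(self):
        # clay holds more plant-available water than sand
        assert bucket_capacity(CLAY) > bucket_capacity(SANDY)


class TestClimateSeries:
    def test_gap_detected(self):
        with pytest.raises(ValueError, match="gap"):
            ClimateSeries(
                months=((2000, 1), (2000, 3)),
                precip=(10.0, 10.0),
                temp_mean=(20.0, 20.0),
            )

    def test_negative_precip_rejected(self):
        with pytest.raises(ValueError, match="precip"):
            ClimateSeries(months=((2000, 1),), precip=(-1.0,),
                          temp_mean=(20.0,))


class TestWaterBalance:
    def test_no_water_in_none_available(self):
        state = ForageState(soil_water=0.0)
        _, eff = water_balance(state, 0.0, SANDY, PARAMS)
        assert eff == 0.0

    def test_saturating_rain_fills_bucket_exactly(self):
        # far more rain than the bucket holds: storage = capacity
        state = ForageState(soil_water=5.0)
        new, _ = water_balance(state, 1000.0, SANDY, PARAMS)
        assert new.soil_water == pytest.approx(bucket_capacity(SANDY))

    def test_negative_precip_is_an_error(self):
        with pytest.raises(ValueError):
            water_balance(ForageState(), -5.0, SANDY, PARAMS)

    @pytest.mark.parametrize("p1,p2,sw0", [(30.0, 0.0, 10.0),
                                           (80.0, 40.0, 0.0),
                                           (5.0, 5.0, 20.0)])
    def test_water_conservation_over_two_months(self, p1, p2, sw0):
        # total moisture extracted can never exceed rain plus what was
        # stored at the start (drainage only loses water)
        state = ForageState(soil_water=sw0)
        state, e1 = water_balance(state, p1, SANDY, PARAMS)
        state, e2 = water_balance(state, p2, SANDY, PARAMS)
        assert e1 + e2 <= p1 + p2 + sw0 + 1e-9

    def test_flux_closure_exact(self):
        # rain = effective + drainage + storage change, to 1e-6 mm
        state = ForageState(soil_water=12.0)
        precip = 60.0
        new, eff = water_balance(state, precip, SANDY, PARAMS)
        residual = ((1 - PARAMS.moisture_uptake_rain) * precip
                    + (1 - PARAMS.moisture_uptake_store) * state.soil_water)
        drainage = max(0.0, residual - bucket_capacity(SANDY))
        delta_store = new.soil_water - state.soil_water
        assert precip == pytest.approx(eff + drainage + delta_store, abs=1e-6)


class TestStepGrowth:
    def test_no_water_means_live_strictly_decreases(self):
        state = ForageState(live_biomass=500.0, dead_biomass=100.0,
                            soil_water=0.0)
        new = step_growth(state, 0.0, 22.0, SANDY, PARAMS)
        assert new.live_biomass < state.live_biomass

    def test_nonfinite_climate_rejected(self):
        with pytest.raises(ValueError):
            step_growth(ForageState(), float("nan"), 22.0, SANDY, PARAMS)

    def test_disabled_feedbacks_make_grazing_history_irrelevant(self):
        params = dataclasses.replace(PARAMS, graze_prod_penalty=0.0,
                                     graze_rootshoot_shift=0.0,
                                     graze_n_boost=0.0)
        grazed = ForageState(live_biomass=400.0, dead_biomass=200.0,
                             soil_water=10.0, last_graze_intensity=0.5)
        ungrazed = dataclasses.replace(grazed, last_graze_intensity=0.0)
        a = step_growth(grazed, 50.0, 22.0, SANDY, params)
        b = step_growth(ungrazed, 50.0, 22.0, SANDY, params)
        assert a == b

    def test_grazing_feedback_reduces_next_month_production(self):
        grazed = ForageState(live_biomass=400.0, dead_biomass=200.0,
                             soil_water=10.0, last_graze_intensity=0.5)
        ungrazed = dataclasses.replace(grazed, last_graze_intensity=0.0)
        _, fg = step_growth(grazed, 50.0, 22.0, SANDY, PARAMS,
                            return_fluxes=True)
        _, fu = step_growth(ungrazed, 50.0, 22.0, SANDY, PARAMS,
                            return_fluxes=True)
        assert fg.production < fu.production

    @pytest.mark.parametrize("precip,temp,live,dead,lgi", [
        (50.0, 22.0, 400.0, 200.0, 0.0),
        (0.0, 30.0, 100.0, 500.0, 0.3),
        (150.0, 18.0, 900.0, 50.0, 1.0),
    ])
    def test_standing_mass_balance(self, precip, temp, live, dead, lgi):
        # d(live+dead) = shoot production - dead decay, to 1e-6 kg/ha
        state = ForageState(live_biomass=live, dead_biomass=dead,
                            soil_water=15.0, last_graze_intensity=lgi)
        new, flux = step_growth(state, precip, temp, SANDY, PARAMS,
                                return_fluxes=True)
        delta = new.standing_biomass - state.standing_biomass
        assert delta == pytest.approx(flux.to_shoot - flux.dead_decay,
                                      abs=1e-6)

    @given(
        precip=st.floats(0, 400),
        temp=st.floats(-5, 45),
        live=st.floats(0, 5000),
        dead=st.floats(0, 5000),
        sw=st.floats(0, 35),
        lgi=st.floats(0, 1),
    )
    @settings(max_examples=200, deadline=None)
    def test_pools_never_negative_and_n_within_bounds(
            self, precip, temp, live, dead, sw, lgi):
        state = ForageState(live_biomass=live, dead_biomass=dead,
                            root_biomass=live, soil_water=sw,
                            last_graze_intensity=lgi)
        new = step_growth(state, precip, temp, SANDY, PARAMS)
        assert new.live_biomass >= 0
        assert new.dead_biomass >= 0
        assert new.root_biomass >= 0
        assert PARAMS.n_live_min <= new.live_n <= PARAMS.n_live_max

    def test_peak_biomass_monotone_in_annual_precip(self):
        # feedbacks off, uniform scaling of all months, temp fixed
        params = dataclasses.replace(PARAMS, graze_prod_penalty=0.0,
                                     graze_rootshoot_shift=0.0,
                                     graze_n_boost=0.0)
        peaks = []
        for annual in (200.0, 400.0, 600.0, 800.0):
            clim = one_year_climatology(annual)
            state = ForageState(live_biomass=100.0, root_biomass=100.0)
            peak = 0.0
            for _ in range(3):
                for i in range(12):
                    state = step_growth(state, clim.precip[i],
                                        clim.temp_mean[i], SANDY, params)
                    peak = max(peak, state.live_biomass)
            peaks.append(peak)
        assert peaks == sorted(peaks)


class TestCrudeProtein:
    def test_standard_factor(self):
        assert crude_protein(0.02) == pytest.approx(0.125)

    def test_zero(self):
        assert crude_protein(0.0) == 0.0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            crude_protein(-0.01)

    def test_round_trip(self):
        cp = crude_protein(0.017)
        assert cp / 6.25 == pytest.approx(0.017)

    def test_live_digestibility_linear_in_n(self):
        p = PARAMS
        assert live_digestibility(p.n_live_max, p) == pytest.approx(
            p.digest_live_max)
        assert live_digestibility(p.n_live_min, p) == pytest.approx(
            p.digest_dead)
        mid = 0.5 * (p.n_live_min + p.n_live_max)
        assert live_digestibility(mid, p) == pytest.approx(
            0.5 * (p.digest_live_max + p.digest_dead))


class TestSpinUp:
    def test_zero_precip_equilibrium_is_bare(self):
        clim = one_year_climatology(0.0)
        res = spin_up(clim, SANDY, PARAMS)
        assert res.state.live_biomass == pytest.approx(0.0, abs=1.0)
        assert res.state.dead_biomass == pytest.approx(0.0, abs=1.0)

    def test_attractor_independent_of_initial_biomass(self, site):
        clim = ClimateSeries(site.climate.months[:12],
                             site.climate.precip[:12],
                             site.climate.temp_mean[:12])
        lo = ForageState(live_biomass=1.0, root_biomass=1.0)
        hi = ForageState(live_biomass=5000.0, dead_biomass=5000.0,
                         root_biomass=5000.0)
        a = spin_up(clim, site.soil, site.grass, initial=lo)
        b = spin_up(clim, site.soil, site.grass, initial=hi)
        assert a.converged and b.converged
        assert a.state.live_biomass == pytest.approx(
            b.state.live_biomass, rel=0.02)

    def test_equilibrium_is_a_fixed_point_of_the_annual_map(self, site):
        clim = ClimateSeries(site.climate.months[:12],
                             site.climate.precip[:12],
                             site.climate.temp_mean[:12])
        res = spin_up(clim, site.soil, site.grass)
        state = res.state
        peaks = []
        for _ in range(2):
            peak = 0.0
            for i in range(12):
                state = step_growth(state, clim.precip[i], clim.temp_mean[i],
                                    site.soil, site.grass)
                peak = max(peak, state.live_biomass)
            peaks.append(peak)
        assert peaks[0] == pytest.approx(peaks[1], rel=0.005)

    def test_wrong_length_climatology_rejected(self, site):
        with pytest.raises(ValueError, match="12 months"):
            spin_up(site.climate, site.soil, site.grass)


class TestApplyOfftake:
    def test_respects_floor(self):
        state = ForageState(live_biomass=300.0, dead_biomass=200.0)
        new = apply_offtake(state, 1000.0, threshold=300.0)
        assert new.standing_biomass == pytest.approx(300.0)

    def test_proportional_across_pools(self):
        state = ForageState(live_biomass=600.0, dead_biomass=400.0)
        new = apply_offtake(state, 100.0)
        assert new.live_biomass == pytest.approx(540.0)
        assert new.dead_biomass == pytest.approx(360.0)
        assert new.last_graze_intensity == pytest.approx(0.1)
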