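"""Gas exchange: vapor pressure, pCO2 chain, Schmidt scaling and fluxes."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oceanch4 import gasex
from oceanch4.gasex import (
    GasExchangeError,
    ch4_equilibrium_concentration,
    ch4_flux,
    co2_flux,
    co2_solubility,
    gas_transfer_velocity,
    pco2_equilibrator,
    pco2_temperature_correction,
    saturation_pct,
    schmidt_number,
    umol_m2_h_to_mmol_m2_d,
    umol_m2_h_to_mmol_m2_y,
    water_vapor_pressure,
)
from oceanch4 import synthetic as syn


class TestWaterVaporPressure:
    def test_hand_check_at_25c_s35(self):
        assert water_vapor_pressure(298.15, 35.0) == pytest.approx(0.0307, abs=2e-4)

    def test_salinity_dependence_is_exponential(self):
        ratio = water_vapor_pressure(298.15, 0.0) / water_vapor_pressure(298.15, 35.0)
        assert ratio == pytest.approx(np.exp(0.000544 * 35.0), rel=1e-12)

    def test_monotone_increasing_in_temperature(self):
        T = np.linspace(271, 319, 200)
        f = water_vapor_pressure(T, 35.0)
        assert np.all(np.diff(f) > 0)

    def test_out_of_range_rejected(self):
        with pytest.raises(GasExchangeError):
            water_vapor_pressure(250.0, 35.0)
        with pytest.raises(GasExchangeError):
            water_vapor_pressure(298.15, 50.0)


class TestPco2Chain:
    def test_identity_limit(self):
        assert pco2_equilibrator(400.0, 0.0, 1.0, 0.0) == pytest.approx(400.0)

    def test_worked_example(self):
        assert pco2_equilibrator(400.0, 0.02, 1.0, 0.03) == pytest.approx(
            400.0 / 0.98 * 0.97, rel=1e-12
        )

    def test_degenerate_limit_f_equals_p(self):
        assert pco2_equilibrator(400.0, 0.02, 1.0, 1.0) == 0.0

    def test_temperature_correction_identity(self):
        assert pco2_temperature_correction(350.0, 18.0, 18.0) == 350.0

    def test_temperature_correction_one_degree(self):
        assert pco2_temperature_correction(350.0, 19.0, 18.0) == pytest.approx(
            350.0 * np.exp(0.0423), rel=1e-12
        )
        assert pco2_temperature_correction(350.0, 19.0, 18.0) == pytest.approx(365.1, abs=0.1)

    def test_correction_inverse_pair(self):
        up = pco2_temperature_correction(350.0, 19.0, 18.0)
        assert pco2_temperature_correction(up, 18.0, 19.0) == pytest.approx(350.0, rel=1e-12)

    def test_sanity_bound_on_warming(self):
        with pytest.raises(GasExchangeError):
            pco2_temperature_correction(350.0, 30.0, 18.0)


class TestSchmidt:
    def test_co2_at_20c_is_668(self):
        assert schmidt_number(20.0, "CO2") == pytest.approx(668.0, abs=1.0)

    def test_strictly_decreasing_on_0_30(self):
        t = np.linspace(0.0, 30.0, 500)
        for gas in ("CO2", "CH4"):
            assert np.all(np.diff(schmidt_number(t, gas)) < 0)

    def test_unknown_gas_rejected(self):
        with pytest.raises(GasExchangeError, match="unknown gas"):
            schmidt_number(20.0, "N2O")


class TestTransferVelocity:
    def test_reference_schmidt_collapses_to_quadratic(self):
        u = 5.0
        assert gas_transfer_velocity(u, 660.0) == pytest.approx(0.251 * u**2, rel=1e-12)

    def test_zero_wind(self):
        assert gas_transfer_velocity(0.0, 660.0) == 0.0

    def test_mean_cruise_wind(self):
        assert gas_transfer_velocity(7.31, 660.0) == pytest.approx(13.41, abs=0.01)


class TestSolubility:
    def test_warmer_water_holds_less_methane(self):
        t = np.linspace(0.0, 30.0, 100)
        c = ch4_equilibrium_concentration(t, 35.0, 1900.0)
        assert np.all(np.diff(c) < 0)

    def test_henry_law_linearity(self):
        c1 = ch4_equilibrium_concentration(20.0, 35.0, 1900.0)
        c2 = ch4_equilibrium_concentration(20.0, 35.0, 3800.0)
        assert c2 == pytest.approx(2 * c1, rel=1e-12)

    def test_positive_output(self):
        assert ch4_equilibrium_concentration(20.0, 35.0, 1900.0) > 0

    def test_co2_kh_plausible_at_20c(self):
        # Weiss-fit seawater K_H near 0.033 mol/l/atm at 20 degC, S=35
        assert co2_solubility(20.0, 35.0) == pytest.approx(0.0332, abs=5e-4)


class TestFluxes:
    def test_zero_at_equilibrium(self):
        assert ch4_flux(10.0, 2.0, 2.0) == 0.0
        assert co2_flux(10.0, 0.03, 0.0) == 0.0

    def test_unit_conversion_example(self):
        # k = 10 cm/h, delta = 1 nmol/l -> 0.1 umol/m2/h = 0.8766 mmol/m2/y
        f = ch4_flux(10.0, 2.0, 1.0)
        assert f == pytest.approx(0.1, rel=1e-12)
        assert umol_m2_h_to_mmol_m2_y(f) == pytest.approx(0.8766, rel=1e-12)

    def test_sink_flux_is_negative(self):
        assert co2_flux(13.4, 0.0332, -55.3) < 0

    @given(
        k=st.floats(min_value=0, max_value=50),
        d=st.floats(min_value=-5, max_value=5),
    )
    @settings(max_examples=50, deadline=None)
    def test_flux_odd_in_disequilibrium(self, k, d):
        assert ch4_flux(k, 2.0 + d, 2.0) == pytest.approx(-ch4_flux(k, 2.0 - d, 2.0), abs=1e-12)
        assert co2_flux(k, 0.03, d) == pytest.approx(-co2_flux(k, 0.03, -d), abs=1e-12)

    def test_unit_round_trips_exact(self):
        f = 1.234
        assert umol_m2_h_to_mmol_m2_y(f) / 8.766 == pytest.approx(f, rel=1e-12)
        assert umol_m2_h_to_mmol_m2_d(f) / 0.024 == pytest.approx(f, rel=1e-12)
        # cm/h <-> m/d
        k_cm_h = 10.0
        assert (k_cm_h * 24 / 100) * 100 / 24 == k_cm_h


class TestSaturation:
    def test_equilibrium_is_100_pct(self):
        assert saturation_pct(2.0, 2.0) == 100.0

    def test_ten_pct_oversaturation(self):
        assert saturation_pct(2.2, 2.0) == pytest.approx(110.0)

    def test_inverse_relation(self):
        assert saturation_pct(2.5, 2.0) / 100.0 * 2.0 == pytest.approx(2.5)


class TestUnderwayChain:
    def test_noise_free_transect_round_trips_exactly(self):
        records, truth = syn.generate_underway(seed=21, n_records=50)
        out = gasex.process_underway(records)
        np.testing.assert_allclose(
            out["pco2_water_uatm"], truth["true_pco2_water_uatm"], rtol=1e-10
        )
        np.testing.assert_allclose(
            out["F_CH4_umol_m2_h"], truth["true_F_CH4_umol_m2_h"], rtol=1e-10
        )
        np.testing.assert_allclose(
            out["F_CO2_umol_m2_h"], truth["true_F_CO2_umol_m2_h"], rtol=1e-10
        )

    def test_zero_wind_means_zero_flux(self):
        records, _ = syn.generate_underway(seed=22, n_records=10, wind_mean=0.0, wind_sd=0.0)
        out = gasex.process_underway(records)
        assert np.all(out["F_CH4_umol_m2_h"] == 0)
        assert np.all(out["F_CO2_umol_m2_h"] == 0)

    def test_no_warming_means_identity_correction(self):
        records, _ = syn.generate_underway(seed=23, n_records=10, warming_c=0.0)
        out = gasex.process_underway(records)
        np.testing.assert_allclose(out["pco2_water_uatm"], out["pco2_eq_uatm"], rtol=1e-12)

    def test_seeded_generation_reproducible(self):
        r1, t1 = syn.generate_underway(seed=24)
        r2, t2 = syn.generate_underway(seed=24)
        assert r1.equals(r2) and t1.equals(t2)
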