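"""Air–sea gas exchange: equilibrator pCO2 corrections and CH4/CO2 fluxes.

The chain implemented here converts shipboard equilibrator measurements to
in situ partial pressures and then to fluxes:

1. ``pCO2(eq) = [xCO2 / (1 - xH2O)] * (P_eq - f)`` — dry mole fraction to
   partial pressure in the equilibrator headspace, with ``f`` the saturated
   water-vapor pressure at the equilibration temperature and salinity,
   ``ln f = 24.4543 - 6745.09/T_eq - 4.8489 ln(T_eq/100) - 0.000544 S``.
2. ``pCO2(water) = pCO2(eq) * exp[0.0423 (SST - T_eq)]`` — correction for
   warming between the seawater intake and the equilibrator.
3. ``k = 0.251 u^2 (Sc/660)^-0.5`` — gas transfer (piston) velocity in
   cm h-1 from the 10-m wind speed ``u`` (m s-1) and the Schmidt number.
4. ``F_CH4 = k (CH4_water - CH4_eq)`` and ``F_CO2 = k K_H dpCO2`` — fluxes,
   positive from sea to air.

Schmidt numbers and the solubility functions (CH4 equilibrium concentration
and CO2 K_H) come from published seawater fits whose coefficients live in
:mod:`oceanch4.gas_constants`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from oceanch4.gas_constants import (
    CH4_SOLUBILITY_COEFFS,
    CO2_KH_COEFFS,
    DAYS_PER_YEAR,
    HOURS_PER_YEAR,
    SC_REFERENCE,
    SCHMIDT_COEFFS,
)


class GasExchangeError(ValueError):
    """Raised for out-of-range or inconsistent gas-exchange inputs."""


# ------------------------------------------------------------------ pCO2 chain

def water_vapor_pressure(t_eq_kelvin, salinity):
    """Saturated water-vapor pressure (atm) over seawater.

    Valid for 270 < T_eq < 320 K and 0 <= S <= 42; inputs outside that
    range raise rather than silently extrapolate.
    """
    T = np.asarray(t_eq_kelvin, dtype=float)
    S = np.asarray(salinity, dtype=float)
    if np.any(T <= 270) or np.any(T >= 320):
        raise GasExchangeError("equilibrator temperature outside 270-320 K")
    if np.any(S < 0) or np.any(S > 42):
        raise GasExchangeError("salinity outside 0-42")
    lnf = 24.4543 - 6745.09 / T - 4.8489 * np.log(T / 100.0) - 0.000544 * S
    out = np.exp(lnf)
    return float(out) if out.ndim == 0 else out


def pco2_equilibrator(xco2_umol_mol, xh2o, p_eq_atm, f_atm):
    """Headspace pCO2 (uatm) from the dry CO2 mole fraction.

    ``xco2_umol_mol`` is the measured dry mole fraction (umol mol-1),
    ``xh2o`` the water-vapor mole fraction in the headspace, ``p_eq_atm``
    the pressure at equilibration and ``f_atm`` the saturated water-vapor
    pressure — all pressures in atm so the result is in uatm.
    """
    xh2o = np.asarray(xh2o, dtype=float)
    if np.any(xh2o < 0) or np.any(xh2o >= 1):
        raise GasExchangeError("xH2O must lie in [0, 1)")
    out = np.asarray(xco2_umol_mol, dtype=float) / (1.0 - xh2o) * (
        np.asarray(p_eq_atm, dtype=float) - np.asarray(f_atm, dtype=float)
    )
    return float(out) if out.ndim == 0 else out


def pco2_temperature_correction(pco2_eq_uatm, sst_c, t_eq_c, max_delta_c: float = 10.0):
    """Correct equilibrator pCO2 to in situ SST (both temperatures degC).

    Uses the standard empirical warming coefficient 0.0423 K-1.  A sanity
    bound rejects |SST - T_eq| >= ``max_delta_c`` as a plumbing error.
    """
    dt = np.asarray(sst_c, dtype=float) - np.asarray(t_eq_c, dtype=float)
    if np.any(np.abs(dt) >= max_delta_c):
        raise GasExchangeError(
            f"|SST - T_eq| >= {max_delta_c} degC; check intake/equilibrator temperatures"
        )
    out = np.asarray(pco2_eq_uatm, dtype=float) * np.exp(0.0423 * dt)
    return float(out) if out.ndim == 0 else out


# ------------------------------------------------------- transfer velocity

def schmidt_number(sst_c, gas: str):
    """Schmidt number of ``gas`` ("CH4" or "CO2") in seawater at SST (degC)."""
    if gas not in SCHMIDT_COEFFS:
        raise GasExchangeError(
            f"unknown gas {gas!r}; known: {sorted(SCHMIDT_COEFFS)}"
        )
    t = np.asarray(sst_c, dtype=float)
    if np.any(t < -2) or np.any(t > 40):
        raise GasExchangeError("SST outside -2..40 degC validity range")
    a, b, c, d, e = SCHMIDT_COEFFS[gas]
    out = a + b * t + c * t**2 + d * t**3 + e * t**4
    return float(out) if out.ndim == 0 else out


def gas_transfer_velocity(u_m_s, sc):
    """Piston velocity k (cm h-1) from the quadratic wind-speed relation."""
    u = np.asarray(u_m_s, dtype=float)
    if np.any(u < 0):
        raise GasExchangeError("wind speed must be non-negative")
    out = 0.251 * u**2 * (np.asarray(sc, dtype=float) / SC_REFERENCE) ** -0.5
    return float(out) if out.ndim == 0 else out


# ------------------------------------------------------------- solubilities

def ch4_equilibrium_concentration(sst_c, salinity, ch4_atm_ppb):
    """Atmospheric-equilibrium dissolved CH4 (nmol l-1).

    Evaluates the seawater CH4 solubility fit at in situ temperature and
    salinity for a dry-air mole fraction given in ppb (nmol mol-1).
    Linear in the atmospheric mole fraction (Henry's law).
    """
    T = np.asarray(sst_c, dtype=float) + 273.15
    S = np.asarray(salinity, dtype=float)
    x = np.asarray(ch4_atm_ppb, dtype=float) * 1e-9
    if np.any(x <= 0):
        raise GasExchangeError("atmospheric CH4 mole fraction must be positive")
    c = CH4_SOLUBILITY_COEFFS
    lnC = (
        np.log(x)
        + c["A1"]
        + c["A2"] * (100.0 / T)
        + c["A3"] * np.log(T / 100.0)
        + c["A4"] * (T / 100.0)
        + S * (c["B1"] + c["B2"] * (T / 100.0) + c["B3"] * (T / 100.0) ** 2)
    )
    out = np.exp(lnC)
    return float(out) if out.ndim == 0 else out


def co2_solubility(sst_c, salinity):
    """CO2 solubility K_H (mol l-1 atm-1) in seawater."""
    T = np.asarray(sst_c, dtype=float) + 273.15
    S = np.asarray(salinity, dtype=float)
    c = CO2_KH_COEFFS
    lnK = (
        c["A1"]
        + c["A2"] * (100.0 / T)
        + c["A3"] * np.log(T / 100.0)
        + S * (c["B1"] + c["B2"] * (T / 100.0) + c["B3"] * (T / 100.0) ** 2)
    )
    out = np.exp(lnK)
    return float(out) if out.ndim == 0 else out


# ------------------------------------------------------------------- fluxes

def umol_m2_h_to_mmol_m2_y(flux):
    """Exact unit conversion: 1 umol m-2 h-1 = 8.766 mmol m-2 y-1."""
    return np.asarray(flux, dtype=float) * HOURS_PER_YEAR / 1000.0


def umol_m2_h_to_mmol_m2_d(flux):
    """Exact unit conversion: 1 umol m-2 h-1 = 0.024 mmol m-2 d-1."""
    return np.asarray(flux, dtype=float) * 24.0 / 1000.0


def ch4_flux(k_gas_cm_h, ch4_water_nmol_l, ch4_equilibrium_nmol_l):
    """Sea–air CH4 flux (umol m-2 h-1), positive out of the sea.

    k in cm h-1 is 0.01 m h-1 per unit, and nmol l-1 equals umol m-3, so
    F[umol m-2 h-1] = 0.01 * k * (CH4_water - CH4_eq).
    """
    out = (
        0.01
        * np.asarray(k_gas_cm_h, dtype=float)
        * (
            np.asarray(ch4_water_nmol_l, dtype=float)
            - np.asarray(ch4_equilibrium_nmol_l, dtype=float)
        )
    )
    return float(out) if np.ndim(out) == 0 else out


def co2_flux(k_gas_cm_h, kh_mol_l_atm, dpco2_uatm):
    """Sea–air CO2 flux (umol m-2 h-1), positive out of the sea.

    K_H * dpCO2 is in umol l-1 = mmol m-3; with k in cm h-1 (0.01 m h-1)
    the product is 0.01 mmol m-2 h-1 = 10 umol m-2 h-1 per unit.
    """
    kh = np.asarray(kh_mol_l_atm, dtype=float)
    if np.any(kh <= 0):
        raise GasExchangeError("K_H must be positive")
    out = 10.0 * np.asarray(k_gas_cm_h, dtype=float) * kh * np.asarray(dpco2_uatm, dtype=float)
    return float(out) if np.ndim(out) == 0 else out


def saturation_pct(ch4_water_nmol_l, ch4_equilibrium_nmol_l):
    """Dissolved CH4 as a percentage of atmospheric equilibrium."""
    eq = np.asarray(ch4_equilibrium_nmol_l, dtype=float)
    if np.any(eq <= 0):
        raise GasExchangeError("equilibrium concentration must be positive")
    out = 100.0 * np.asarray(ch4_water_nmol_l, dtype=float) / eq
    return float(out) if np.ndim(out) == 0 else out


# ------------------------------------------------------------ record chain

def process_underway(records: pd.DataFrame) -> pd.DataFrame:
    """Run the full chain over an underway table, keeping intermediates.

    Required columns: SST_c, S, xCO2_umol_mol, xH2O, P_eq_atm, T_eq_K,
    u_m_s, ch4_water_nmol_l, ch4_atm_ppb, pco2_atm_uatm.  Optional: time,
    lat, lon (carried through).

    Returns one row per record with f (atm), pCO2_eq and pCO2_water (uatm),
    dpCO2, Sc for both gases, piston velocities (cm h-1), K_H, the CH4
    equilibrium concentration and saturation, and CH4/CO2 fluxes in
    umol m-2 h-1, mmol m-2 d-1 and mmol m-2 y-1.
    """
    out = records.loc[:, [c for c in ("time", "lat", "lon") if c in records.columns]].copy()
    sst = records["SST_c"].to_numpy(dtype=float)
    sal = records["S"].to_numpy(dtype=float)
    t_eq_K = records["T_eq_K"].to_numpy(dtype=float)
    t_eq_C = t_eq_K - 273.15

    f = water_vapor_pressure(t_eq_K, sal)
    pco2_eq = pco2_equilibrator(
        records["xCO2_umol_mol"].to_numpy(dtype=float),
        records["xH2O"].to_numpy(dtype=float),
        records["P_eq_atm"].to_numpy(dtype=float),
        f,
    )
    pco2_water = pco2_temperature_correction(pco2_eq, sst, t_eq_C)
    dpco2 = pco2_water - records["pco2_atm_uatm"].to_numpy(dtype=float)

    sc_ch4 = schmidt_number(sst, "CH4")
    sc_co2 = schmidt_number(sst, "CO2")
    u = records["u_m_s"].to_numpy(dtype=float)
    k_ch4 = gas_transfer_velocity(u, sc_ch4)
    k_co2 = gas_transfer_velocity(u, sc_co2)

    ch4_w = records["ch4_water_nmol_l"].to_numpy(dtype=float)
    ch4_eq = ch4_equilibrium_concentration(sst, sal, records["ch4_atm_ppb"].to_numpy(dtype=float))
    kh = co2_solubility(sst, sal)

    f_ch4 = ch4_flux(k_ch4, ch4_w, ch4_eq)
    f_co2 = co2_flux(k_co2, kh, dpco2)

    out["f_atm"] = f
    out["pco2_eq_uatm"] = pco2_eq
    out["pco2_water_uatm"] = pco2_water
    out["dpco2_uatm"] = dpco2
    out["Sc_CH4"] = sc_ch4
    out["Sc_CO2"] = sc_co2
    out["k_CH4_cm_h"] = k_ch4
    out["k_CO2_cm_h"] = k_co2
    out["KH_mol_l_atm"] = kh
    out["ch4_equilibrium_nmol_l"] = ch4_eq
    out["ch4_saturation_pct"] = saturation_pct(ch4_w, ch4_eq)
    out["F_CH4_umol_m2_h"] = f_ch4
    out["F_CH4_mmol_m2_d"] = umol_m2_h_to_mmol_m2_d(f_ch4)
    out["F_CH4_mmol_m2_y"] = umol_m2_h_to_mmol_m2_y(f_ch4)
    out["F_CO2_umol_m2_h"] = f_co2
    out["F_CO2_mmol_m2_d"] = umol_m2_h_to_mmol_m2_d(f_co2)
    out["F_CO2_mmol_m2_y"] = umol_m2_h_to_mmol_m2_y(f_co2)
    return out
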