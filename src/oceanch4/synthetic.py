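"""Synthetic cruise data with known ground truth.

Generates every input table the analysis stages consume — station property
sections, tracer incubation counts, underway transects and amendment
incubation time courses — from configurable scenarios whose truth (mixing
fractions, rate constants, fluxes, production rates) is returned alongside,
so each downstream stage can be tested for recovery without any download.

The default scenarios emulate a western-boundary mixing region where a warm,
saline, nutrient-poor subtropical current (Kuroshio-like) meets a cold,
fresh, nutrient-rich subarctic current (Oyashio-like): meridional surface
gradients of roughly 17-30 degC and salinity 33.2-35.1, dissolved CH4
decreasing from ~6.1 nmol/l in the fresh endmember to ~5.2 nmol/l in the
saline one, and winds near 7.3 +/- 1.4 m/s.  Endmember property values are
configuration, not constants.

Randomness: a single scenario seed fans out to independent substreams (via
``numpy.random.SeedSequence.spawn``) so stages are reproducible in
isolation.  Measurement noise is independent Gaussian per property;
scintillation counting noise is Gaussian with sd = sqrt(DPM) (the Poisson
approximation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from oceanch4 import gasex
from oceanch4.omp import PROPERTIES, EndmemberSet

__all__ = [
    "ScenarioConfig",
    "default_endmembers",
    "default_scenario",
    "generate_section",
    "generate_tracer_incubations",
    "generate_tracer_survey",
    "generate_underway",
    "generate_amendment_timeseries",
    "generate_budget_region",
]


class SyntheticError(ValueError):
    pass


def default_endmembers(n: int = 2) -> tuple[EndmemberSet, np.ndarray]:
    """Kuroshio/Oyashio-style endmembers (+ intermediate water for n=3).

    Returns the endmember set and per-endmember dissolved CH4 (nmol/l).
    Property values are plausible for the Northwest Pacific upper water
    column and are meant to be replaced by users with their own endmember
    table.
    """
    #                 T      S     O     P     N     Si
    kuroshio = [22.0, 34.8, 210.0, 0.20, 1.5, 3.0]
    oyashio = [5.0, 33.2, 310.0, 1.80, 22.0, 40.0]
    npiw = [6.0, 34.2, 120.0, 2.40, 35.0, 80.0]
    if n == 2:
        ems = EndmemberSet(("Kuroshio", "Oyashio"), np.array([kuroshio, oyashio]))
        ch4 = np.array([5.15, 6.11])
    elif n == 3:
        ems = EndmemberSet(
            ("Kuroshio", "Oyashio", "NPIW"), np.array([kuroshio, oyashio, npiw])
        )
        ch4 = np.array([5.15, 6.11, 1.50])
    else:
        raise SyntheticError("default scenarios define 2 or 3 endmembers")
    return ems, ch4


@dataclass
class ScenarioConfig:
    """Full specification of a synthetic station section.

    ``mixing_profile`` has shape (n_stations, n_depths, n_endmembers); each
    fraction vector must be non-negative and sum to 1.  ``noise_sd`` maps
    property name to the measurement noise sd in native units (unlisted
    properties get 0).  ``production_anomaly`` (nmol/l) is added to the
    conservative CH4 field; negative values model net consumption.
    """

    seed: int
    endmembers: EndmemberSet
    ch4_endmember: np.ndarray  # nmol/l per endmember
    n_stations: int = 20
    depths: tuple = (5.0, 25.0, 50.0, 75.0, 100.0, 150.0, 200.0, 300.0)
    mixing_profile: np.ndarray | None = None
    noise_sd: dict = field(default_factory=dict)
    ch4_noise_sd: float = 0.0
    production_anomaly: float | np.ndarray = 0.0
    true_k: float = 0.013  # d-1, tracer simulation
    wind_mean: float = 7.31  # m/s
    wind_sd: float = 1.38

    def __post_init__(self) -> None:
        self.ch4_endmember = np.asarray(self.ch4_endmember, dtype=float)
        if self.ch4_endmember.shape != (self.endmembers.n_endmembers,):
            raise SyntheticError("ch4_endmember must give one value per endmember")
        z = np.asarray(self.depths, dtype=float)
        if np.any(np.diff(z) <= 0):
            raise SyntheticError("depths must be strictly increasing")
        for p, sd in self.noise_sd.items():
            if p not in PROPERTIES:
                raise SyntheticError(f"unknown property in noise_sd: {p!r}")
            if sd < 0:
                raise SyntheticError("noise_sd values must be >= 0")
        if self.mixing_profile is None:
            self.mixing_profile = _default_mixing_profile(
                self.n_stations, len(self.depths), self.endmembers.n_endmembers
            )
        self.mixing_profile = np.asarray(self.mixing_profile, dtype=float)
        expected = (self.n_stations, len(self.depths), self.endmembers.n_endmembers)
        if self.mixing_profile.shape != expected:
            raise SyntheticError(
                f"mixing_profile shape {self.mixing_profile.shape} != {expected}"
            )
        bad = ~(
            np.all(self.mixing_profile >= 0, axis=2)
            & np.isclose(self.mixing_profile.sum(axis=2), 1.0)
        )
        if np.any(bad):
            i, j = np.argwhere(bad)[0]
            raise SyntheticError(
                f"fraction vector at station {i}, depth {self.depths[j]} m is not on "
                f"the simplex: {self.mixing_profile[i, j]}"
            )

    def noise_vector(self) -> np.ndarray:
        return np.array([float(self.noise_sd.get(p, 0.0)) for p in PROPERTIES])


def _default_mixing_profile(n_stations: int, n_depths: int, n_em: int) -> np.ndarray:
    """Smooth meridional gradient: endmember 1 dominates the 'south' end."""
    s = np.linspace(-3.0, 3.0, n_stations)
    frac1 = 1.0 / (1.0 + np.exp(s))  # 1 -> 0 across the section
    profile = np.zeros((n_stations, n_depths, n_em))
    zfade = np.linspace(1.0, 0.6, n_depths)  # endmember 1 shallower
    for i in range(n_stations):
        for j in range(n_depths):
            f1 = frac1[i] * zfade[j]
            if n_em == 2:
                profile[i, j] = (f1, 1.0 - f1)
            else:
                # deep water gains the third endmember
                f3 = (1.0 - zfade[j]) * 0.8
                profile[i, j] = (f1 * (1 - f3), (1.0 - f1) * (1 - f3), f3)
                profile[i, j] /= profile[i, j].sum()
    return profile


def default_scenario(seed: int = 0, n_endmembers: int = 2, **overrides) -> ScenarioConfig:
    """Measurement-scale noise scenario with the default endmembers."""
    ems, ch4 = default_endmembers(n_endmembers)
    noise = {"T": 0.05, "S": 0.01, "O": 2.0, "P": 0.02, "N": 0.2, "Si": 0.5}
    cfg = dict(
        seed=seed,
        endmembers=ems,
        ch4_endmember=ch4,
        noise_sd=noise,
        ch4_noise_sd=0.05,
    )
    cfg.update(overrides)
    return ScenarioConfig(**cfg)


def generate_section(config: ScenarioConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Property section plus ground truth.

    Each sample's six properties are the fraction-weighted endmember
    properties plus Gaussian noise; CH4 is the conservative mixture of the
    per-endmember CH4 values plus ``production_anomaly``.

    Returns ``(samples, truth)``: samples in the 'stations' schema, truth
    with the true fraction per endmember and the conservative CH4.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    ems = config.endmembers
    noise = config.noise_vector()
    anomaly = np.broadcast_to(
        np.asarray(config.production_anomaly, dtype=float),
        (config.n_stations, len(config.depths)),
    )
    samples, truth = [], []
    for i in range(config.n_stations):
        for j, z in enumerate(config.depths):
            x = config.mixing_profile[i, j]
            props = x @ ems.properties + rng.normal(0.0, noise)
            ch4_cons = float(x @ config.ch4_endmember)
            ch4 = ch4_cons + anomaly[i, j]
            if config.ch4_noise_sd > 0:
                ch4 += rng.normal(0.0, config.ch4_noise_sd)
            samples.append(
                {
                    "station": f"S{i + 1:02d}",
                    "depth_m": float(z),
                    **{p: props[k] for k, p in enumerate(PROPERTIES)},
                    "ch4_nmol_l": ch4,
                }
            )
            truth.append(
                {
                    "station": f"S{i + 1:02d}",
                    "depth_m": float(z),
                    **{f"frac_{n}": x[k] for k, n in enumerate(ems.names)},
                    "ch4_conservative": ch4_cons,
                    "production_anomaly": float(anomaly[i, j]),
                }
            )
    return pd.DataFrame(samples), pd.DataFrame(truth)


def generate_tracer_incubations(
    true_k: float,
    ch4: float,
    t: float = 2.0,
    dpm_total: float = 1e5,
    n_reps: int = 3,
    seed: int = 0,
    background_dpm: float = 30.0,
    counting_noise: bool = True,
    station="S01",
    depth_m: float = 5.0,
) -> pd.DataFrame:
    """Triplicate (or n_reps) tracer incubations plus a killed control.

    The live product count is ``true_k * t * dpm_total`` plus counting noise
    (sd = sqrt of the expected count); the killed control sits at the
    background level.  ``true_k * t`` must not exceed 1 (the oxidized
    fraction cannot exceed the pool).
    """
    if not 0.0 <= true_k * t <= 1.0:
        raise SyntheticError(f"true_k*t = {true_k * t} outside [0, 1]")
    if dpm_total <= 0:
        raise SyntheticError("dpm_total must be positive")
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(2)[1])
    rows = []
    for rep in range(1, n_reps + 1):
        expected = true_k * t * dpm_total + background_dpm
        product = float(expected)
        total = float(dpm_total)
        if counting_noise:
            product += rng.normal(0.0, np.sqrt(max(expected, 1.0)))
            total += rng.normal(0.0, np.sqrt(dpm_total))
        product = float(np.clip(product, 0.0, total))
        rows.append(
            {
                "station": station,
                "depth_m": depth_m,
                "replicate": rep,
                "is_control": False,
                "dpm_product": product,
                "dpm_total": total,
                "t_days": t,
                "ch4_nmol_l": ch4,
            }
        )
    ctrl = float(background_dpm)
    total = float(dpm_total)
    if counting_noise:
        ctrl += rng.normal(0.0, np.sqrt(max(background_dpm, 1.0)))
        total += rng.normal(0.0, np.sqrt(dpm_total))
    rows.append(
        {
            "station": station,
            "depth_m": depth_m,
            "replicate": 0,
            "is_control": True,
            "dpm_product": float(np.clip(ctrl, 0.0, total)),
            "dpm_total": total,
            "t_days": t,
            "ch4_nmol_l": ch4,
        }
    )
    return pd.DataFrame(rows)


def generate_tracer_survey(
    stations: list,
    true_k,
    ch4,
    depths=(5.0,),
    seed: int = 0,
    **kwargs,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tracer incubation sets for many stations/depths.

    ``true_k`` and ``ch4`` may be scalars or per-station arrays.  Returns
    the replicate table and a truth table of the per-station k and MOx.
    """
    k_arr = np.broadcast_to(np.asarray(true_k, dtype=float), (len(stations),))
    c_arr = np.broadcast_to(np.asarray(ch4, dtype=float), (len(stations),))
    seeds = np.random.SeedSequence(seed).spawn(len(stations) * len(depths))
    tables, truth = [], []
    si = 0
    for i, st in enumerate(stations):
        for z in depths:
            child_seed = int(seeds[si].generate_state(1)[0])
            tables.append(
                generate_tracer_incubations(
                    float(k_arr[i]),
                    float(c_arr[i]),
                    seed=child_seed,
                    station=st,
                    depth_m=float(z),
                    **kwargs,
                )
            )
            si += 1
            truth.append(
                {
                    "station": st,
                    "depth_m": float(z),
                    "true_k": float(k_arr[i]),
                    "true_mox": float(k_arr[i] * c_arr[i]),
                }
            )
    return pd.concat(tables, ignore_index=True), pd.DataFrame(truth)


def generate_underway(
    seed: int = 0,
    n_records: int = 200,
    lat_south: float = 35.0,
    lat_north: float = 41.0,
    sst_south: float = 30.2,
    sst_north: float = 16.8,
    sal_south: float = 35.1,
    sal_north: float = 33.2,
    pco2_south: float = 360.0,
    pco2_north: float = 338.0,
    ch4_south: float = 5.15,
    ch4_north: float = 6.11,
    ch4_atm_ppb: float = 1900.0,
    dpco2_atm_uatm: float = 55.3,
    wind_mean: float = 7.31,
    wind_sd: float = 1.38,
    warming_c: float = 0.5,
    p_eq_atm: float = 1.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Underway transect with meridional gradients and known true fluxes.

    Fields vary linearly with latitude between the stated south/north
    values; wind is drawn once per record around ``wind_mean``.  The raw
    instrument quantities (xCO2, xH2O, T_eq) are constructed by inverting
    the pCO2 correction chain from the target in situ pCO2, so processing
    the records reproduces the true fields exactly (the generator adds no
    measurement noise; gradients are the signal).

    Returns ``(records, truth)`` where truth holds the true pCO2(water),
    fluxes and saturation per record.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(3)[2])
    lat = np.linspace(lat_south, lat_north, n_records)
    w = (lat - lat_south) / (lat_north - lat_south)  # 0 south -> 1 north
    sst = sst_south + w * (sst_north - sst_south)
    sal = sal_south + w * (sal_north - sal_south)
    pco2_water = pco2_south + w * (pco2_north - pco2_south)
    ch4_water = ch4_south + w * (ch4_north - ch4_south)
    u = np.clip(rng.normal(wind_mean, wind_sd, n_records), 0.0, None)

    t_eq_c = sst + warming_c
    t_eq_k = t_eq_c + 273.15
    f = gasex.water_vapor_pressure(t_eq_k, sal)
    pco2_eq = pco2_water / np.exp(0.0423 * (sst - t_eq_c))
    xh2o = f / p_eq_atm  # saturated headspace
    xco2 = pco2_eq * (1.0 - xh2o) / (p_eq_atm - f)
    pco2_atm = pco2_water + dpco2_atm_uatm  # sea is a CO2 sink

    records = pd.DataFrame(
        {
            "time": np.arange(n_records, dtype=float),
            "lat": lat,
            "lon": np.full(n_records, 150.0),
            "SST_c": sst,
            "S": sal,
            "xCO2_umol_mol": xco2,
            "xH2O": xh2o,
            "P_eq_atm": np.full(n_records, p_eq_atm),
            "T_eq_K": t_eq_k,
            "u_m_s": u,
            "ch4_water_nmol_l": ch4_water,
            "ch4_atm_ppb": np.full(n_records, ch4_atm_ppb),
            "pco2_atm_uatm": pco2_atm,
        }
    )
    ch4_eq = gasex.ch4_equilibrium_concentration(sst, sal, ch4_atm_ppb)
    k_ch4 = gasex.gas_transfer_velocity(u, gasex.schmidt_number(sst, "CH4"))
    k_co2 = gasex.gas_transfer_velocity(u, gasex.schmidt_number(sst, "CO2"))
    kh = gasex.co2_solubility(sst, sal)
    truth = pd.DataFrame(
        {
            "lat": lat,
            "true_pco2_water_uatm": pco2_water,
            "true_dpco2_uatm": np.full(n_records, -dpco2_atm_uatm),
            "true_F_CH4_umol_m2_h": gasex.ch4_flux(k_ch4, ch4_water, ch4_eq),
            "true_F_CO2_umol_m2_h": gasex.co2_flux(k_co2, kh, -dpco2_atm_uatm),
            "true_saturation_pct": gasex.saturation_pct(ch4_water, ch4_eq),
        }
    )
    return records, truth


def generate_amendment_timeseries(
    baseline: float,
    rate: float,
    lag: float,
    t_points,
    noise_sd: float = 0.0,
    seed: int = 0,
    n_reps: int = 3,
    treatment_label: str = "treatment",
) -> pd.DataFrame:
    """Amendment incubation time course (treatment + unamended control).

    Control replicates stay flat at ``baseline``; treatment replicates stay
    flat until ``lag`` days then rise linearly at ``rate`` nmol/l/d.
    Concentrations that come out negative after noise are clipped at 0 and
    flagged in a ``clipped`` column.
    """
    t = np.asarray(t_points, dtype=float)
    if lag < 0:
        raise SyntheticError("lag must be >= 0")
    if np.any(np.diff(t) <= 0):
        raise SyntheticError("t_points must be strictly increasing")
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(4)[3])
    rows = []
    for label, is_treatment in ((treatment_label, True), ("control", False)):
        for rep in range(1, n_reps + 1):
            mean = np.full(t.size, baseline)
            if is_treatment:
                mean = mean + rate * np.clip(t - lag, 0.0, None)
            ch4 = mean + (rng.normal(0.0, noise_sd, t.size) if noise_sd > 0 else 0.0)
            clipped = ch4 < 0
            ch4 = np.clip(ch4, 0.0, None)
            for ti, ci, fi in zip(t, ch4, clipped):
                rows.append(
                    {
                        "treatment": label,
                        "replicate": rep,
                        "t_days": float(ti),
                        "ch4_nmol_l": float(ci),
                        "clipped": bool(fi),
                    }
                )
    return pd.DataFrame(rows)


def generate_budget_region(
    seed: int = 0,
    n_stations: int = 12,
    true_mean_fraction: float = 0.437,
    fraction_spread: float = 0.20,
    depths=(5.0, 50.0, 100.0, 150.0, 200.0, 300.0),
    mean_mox_nmol_l_d: float = 0.044,
    noise_rel_sd: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Station MOx profiles and fluxes built around a known MOx share.

    Per-station true MOx fractions are deterministic normal quantiles with
    the stated mean and spread (clipped away from 0 and 1, then recentred so
    the construction mean is exact); the sea-air flux of each station is set
    so that integral(MOx)/(integral(MOx)+flux) equals its true fraction, and
    multiplicative Gaussian noise at ``noise_rel_sd`` is then applied to
    both loss terms.

    Returns ``(mox_profiles, fluxes, truth)`` ready for
    :func:`oceanch4.budget.station_budgets`.
    """
    from scipy import stats as _stats

    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(5)[4])
    q = (np.arange(n_stations) + 0.5) / n_stations
    f_true = true_mean_fraction + fraction_spread * _stats.norm.ppf(q)
    f_true = np.clip(f_true, 0.05, 0.95)
    f_true += true_mean_fraction - f_true.mean()  # exact construction mean

    z = np.asarray(depths, dtype=float)
    profiles, fluxes, truth = [], [], []
    for i in range(n_stations):
        st = f"B{i + 1:02d}"
        # gentle decay of MOx with depth around the stated mean
        shape = np.exp(-z / 400.0)
        rates = mean_mox_nmol_l_d * shape / shape.mean()
        noisy = rates * np.clip(rng.normal(1.0, noise_rel_sd, z.size), 0.0, None)
        # integral of the noiseless profile with surface extension, umol/m2/d
        zz = np.insert(z, 0, 0.0)
        rr = np.insert(rates, 0, rates[0])
        integ_true = float(np.trapezoid(rr, zz))
        integ_true_y = integ_true * 365.25 / 1000.0  # mmol/m2/y
        flux_true = integ_true_y * (1.0 / f_true[i] - 1.0)
        flux_noisy = flux_true * float(np.clip(rng.normal(1.0, noise_rel_sd), 0.0, None))
        for zi, ri in zip(z, noisy):
            profiles.append({"station": st, "depth_m": float(zi), "mox_nmol_l_d": float(ri)})
        fluxes.append({"station": st, "F_CH4_mmol_m2_y": flux_noisy})
        truth.append(
            {
                "station": st,
                "true_fraction_pct": 100.0 * f_true[i],
                "true_integrated_mox_mmol_m2_y": integ_true_y,
                "true_flux_mmol_m2_y": flux_true,
            }
        )
    return pd.DataFrame(profiles), pd.DataFrame(fluxes), pd.DataFrame(truth)
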