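"""Depth-integrated methane loss budget.

The water-column methane budget considered here has exactly two loss terms:
microbial oxidation (MOx), depth-integrated over the upper water column, and
sea-to-air emission.  The microbial share of total methane removal is::

    mox_fraction = 100 * integral(MOx) / (integral(MOx) + F_CH4)    [%]

Volumetric rates in nmol l-1 d-1 equal umol m-3 d-1, so a trapezoidal
integral over depth (m) yields umol m-2 d-1 directly.  The default
integration depth is 300 m, matching the upper-water-column framing used
for per-water-mass comparisons; it is configurable.  When the sea is a CH4
sink (negative flux) the flux contributes nothing to removal and is floored
at zero with a flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from oceanch4.gas_constants import DAYS_PER_YEAR

logger = logging.getLogger(__name__)

DEFAULT_INTEGRATION_DEPTH_M = 300.0


class BudgetError(ValueError):
    pass


def depth_integrate(
    depths_m,
    rates_nmol_l_d,
    z_max: float = DEFAULT_INTEGRATION_DEPTH_M,
) -> dict:
    """Trapezoidal depth integral of a volumetric rate profile.

    ``depths_m`` must be strictly increasing (positive downward).  The
    profile is extended to the surface with the shallowest value (flagged),
    and cut at ``z_max`` by linear interpolation; ``z_max`` beyond the
    deepest sample is an error rather than an extrapolation.

    Returns a dict with the integral in umol m-2 d-1 and mmol m-2 y-1 plus
    the surface-extension flag.
    """
    z = np.asarray(depths_m, dtype=float)
    r = np.asarray(rates_nmol_l_d, dtype=float)
    if z.size < 2:
        raise BudgetError("need at least 2 depths")
    if np.any(np.diff(z) <= 0):
        raise BudgetError("depths must be strictly increasing")
    if z_max <= z[0]:
        raise BudgetError(f"z_max={z_max} m is above the shallowest sample ({z[0]} m)")
    if z_max > z[-1]:
        raise BudgetError(f"z_max={z_max} m is below the deepest sample ({z[-1]} m)")
    if np.any(r < 0):
        raise BudgetError("negative rates are unphysical for MOx profiles")

    surface_extended = z[0] > 0
    if surface_extended:
        z = np.insert(z, 0, 0.0)
        r = np.insert(r, 0, r[0])
        logger.info("profile extended to the surface with the shallowest value")
    if z_max < z[-1]:
        r_zmax = float(np.interp(z_max, z, r))
        keep = z < z_max
        z = np.append(z[keep], z_max)
        r = np.append(r[keep], r_zmax)

    integral_umol_m2_d = float(np.trapezoid(r, z))  # nmol/l = umol/m3
    return {
        "umol_m2_d": integral_umol_m2_d,
        "mmol_m2_y": integral_umol_m2_d * DAYS_PER_YEAR / 1000.0,
        "surface_extended": bool(surface_extended),
        "z_max_m": float(z_max),
    }


def mox_fraction(integrated_mox, flux_ch4) -> tuple[float, bool]:
    """Microbial share (%) of total methane removal.

    Both inputs must be in the same areal units.  A negative sea–air flux
    (uptake) is floored at 0 for this ratio and flagged, since removal sums
    two loss terms.  Scale-invariant in its inputs.

    Returns ``(fraction_pct, flux_floored_flag)``.
    """
    mox = float(integrated_mox)
    flux = float(flux_ch4)
    if mox < 0:
        raise BudgetError("depth-integrated MOx must be non-negative")
    floored = flux < 0
    if floored:
        logger.info("negative sea-air flux floored at 0 in removal total")
        flux = 0.0
    if mox == 0 and flux == 0:
        raise BudgetError("both loss terms are zero; fraction undefined")
    return 100.0 * mox / (mox + flux), floored


@dataclass
class StationBudget:
    station: object
    integrated_mox_umol_m2_d: float
    integrated_mox_mmol_m2_y: float
    flux_ch4_mmol_m2_y: float
    mox_fraction_pct: float
    flux_floored: bool
    integration_depth_m: float


def station_budgets(
    mox_profiles: pd.DataFrame,
    fluxes: pd.DataFrame,
    z_max: float = DEFAULT_INTEGRATION_DEPTH_M,
) -> pd.DataFrame:
    """Per-station methane loss budgets.

    ``mox_profiles`` columns: station, depth_m, mox_nmol_l_d.
    ``fluxes`` columns: station, F_CH4_mmol_m2_y.

    Returns one row per station present in both tables, with the
    depth-integrated MOx (per day and per year), the sea–air flux, and the
    MOx share of total removal.
    """
    flux_by_station = fluxes.set_index("station")["F_CH4_mmol_m2_y"]
    rows = []
    for station, grp in mox_profiles.groupby("station", sort=False):
        if station not in flux_by_station.index:
            logger.warning("station %r has no flux record; skipped", station)
            continue
        grp = grp.sort_values("depth_m")
        integ = depth_integrate(grp["depth_m"], grp["mox_nmol_l_d"], z_max=z_max)
        flux = float(flux_by_station[station])
        frac, floored = mox_fraction(integ["mmol_m2_y"], flux)
        rows.append(
            {
                "station": station,
                "integrated_mox_umol_m2_d": integ["umol_m2_d"],
                "integrated_mox_mmol_m2_y": integ["mmol_m2_y"],
                "flux_ch4_mmol_m2_y": flux,
                "mox_fraction_pct": frac,
                "flux_floored": floored,
                "integration_depth_m": z_max,
            }
        )
    return pd.DataFrame(rows)


def regional_summary(budgets: pd.DataFrame, grouping: str | None = None) -> pd.DataFrame:
    """Mean +/- sample sd of budget fields, overall or per group.

    ``grouping`` names a column of ``budgets`` (e.g. a water-mass label or
    latitude band).  Single-station groups report sd as NaN.
    """
    numeric = [
        c
        for c in (
            "integrated_mox_umol_m2_d",
            "integrated_mox_mmol_m2_y",
            "flux_ch4_mmol_m2_y",
            "mox_fraction_pct",
        )
        if c in budgets.columns
    ]
    if budgets.empty:
        raise BudgetError("no station budgets to summarize")

    def agg(g: pd.DataFrame) -> pd.Series:
        out = {}
        for c in numeric:
            out[f"{c}_mean"] = g[c].mean()
            out[f"{c}_sd"] = g[c].std(ddof=1) if len(g) > 1 else np.nan
        out["n_stations"] = len(g)
        return pd.Series(out)

    if grouping is None:
        return agg(budgets).to_frame().T
    return budgets.groupby(grouping, sort=False).apply(agg, include_groups=False).reset_index()
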