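"""Radiotracer methane-oxidation (MOx) kinetics.

Aerobic methane oxidation in seawater incubations spiked with tritiated
methane follows first-order kinetics at trace-level additions.  The fraction
of the tracer pool turned over during an incubation of length ``t`` (days)
gives the rate constant::

    k = DPM(3H-H2O) / DPM(3H-H2O + 3H-CH4) * 1/t        [d-1]

and the volumetric oxidation rate is the rate constant applied to the
ambient methane pool::

    MOx = k * [CH4]_in_situ                              [nmol l-1 d-1]

where DPM are scintillation counts (disintegrations per minute) of the
oxidation product (tritiated water, after purging residual tracer gas) and
of the total tracer, and [CH4]_in_situ is measured in separate vials.
Killed (formalin-poisoned) controls quantify abiotic tracer turnover; their
turnover fraction is subtracted on the fraction scale before forming k.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class TracerError(ValueError):
    """Raised for physically inconsistent tracer counts."""


@dataclass(frozen=True)
class TracerIncubation:
    """One scintillation-counted incubation replicate."""

    dpm_product: float  # DPM of 3H-H2O after purging
    dpm_total: float  # DPM of 3H-H2O + 3H-CH4
    t_days: float
    ch4_in_situ: float = np.nan  # nmol l-1
    is_killed_control: bool = False
    replicate: object = None
    station: object = None
    depth_m: float = np.nan

    def __post_init__(self) -> None:
        if self.dpm_total <= 0:
            raise TracerError("dpm_total must be positive")
        if self.dpm_product < 0:
            raise TracerError("dpm_product cannot be negative")
        if self.dpm_product > self.dpm_total:
            raise TracerError(
                "dpm_product exceeds dpm_total (contamination or purge failure): "
                f"{self.dpm_product} > {self.dpm_total}"
            )
        if self.t_days <= 0:
            raise TracerError("incubation time must be positive")

    @property
    def turnover_fraction(self) -> float:
        """Fraction of the tracer pool oxidized during the incubation."""
        return self.dpm_product / self.dpm_total


def rate_constant(inc: TracerIncubation) -> float:
    """First-order rate constant k (d-1) from one incubation.

    k is the turnover fraction divided by the incubation time and is
    invariant to rescaling both DPM readings by a common factor.
    """
    return inc.turnover_fraction / inc.t_days


def control_correct(
    samples: list[TracerIncubation],
    control: TracerIncubation,
) -> tuple[list[float], list[bool]]:
    """Subtract the killed control's turnover fraction from live samples.

    The correction acts on the turnover-fraction scale (what is actually
    counted); corrected fractions that come out negative are clipped to 0
    and flagged.  All incubations must share the incubation time.

    Returns ``(corrected_fractions, clipped_flags)`` aligned with samples.
    """
    if not control.is_killed_control:
        raise TracerError("control incubation is not marked as a killed control")
    for s in samples:
        if not np.isclose(s.t_days, control.t_days):
            raise TracerError(
                "control and samples must share incubation time "
                f"({s.t_days} vs {control.t_days} d)"
            )
    cf = control.turnover_fraction
    corrected, clipped = [], []
    for s in samples:
        f = s.turnover_fraction - cf
        if f < 0:
            corrected.append(0.0)
            clipped.append(True)
        else:
            corrected.append(f)
            clipped.append(False)
    if corrected and all(clipped):
        logger.warning(
            "killed-control turnover exceeds every live sample; all rates zero "
            "(station=%r)",
            control.station,
        )
    return corrected, clipped


def mox_rate(k: float, ch4_in_situ: float) -> float:
    """MOx rate (nmol l-1 d-1) = k (d-1) x in situ CH4 (nmol l-1)."""
    if k < 0:
        raise TracerError("rate constant must be non-negative")
    if ch4_in_situ < 0:
        raise TracerError("CH4 concentration must be non-negative")
    return k * ch4_in_situ


def estimate_mox(
    table: pd.DataFrame,
    correct_with_control: bool = True,
) -> pd.DataFrame:
    """Per-station/depth MOx estimates from a replicate-level table.

    ``table`` columns: station, depth_m, replicate, is_control, dpm_product,
    dpm_total, t_days, ch4_nmol_l.  Each station/depth group should contain
    live replicates and (optionally) one killed control.

    Returns one row per station/depth with k and MOx means, sample standard
    deviations across replicates, replicate count, the control turnover
    fraction used, and a flag for clipped (negative-corrected) replicates.
    """
    required = {
        "station",
        "depth_m",
        "replicate",
        "is_control",
        "dpm_product",
        "dpm_total",
        "t_days",
        "ch4_nmol_l",
    }
    missing = required - set(table.columns)
    if missing:
        raise TracerError(f"tracer table missing columns: {sorted(missing)}")

    rows = []
    for (station, depth), grp in table.groupby(["station", "depth_m"], sort=False):
        live = grp[~grp["is_control"].astype(bool)]
        ctrl = grp[grp["is_control"].astype(bool)]
        incs = [
            TracerIncubation(
                dpm_product=float(r.dpm_product),
                dpm_total=float(r.dpm_total),
                t_days=float(r.t_days),
                ch4_in_situ=float(r.ch4_nmol_l),
                replicate=r.replicate,
                station=station,
                depth_m=depth,
            )
            for r in live.itertuples()
        ]
        if not incs:
            logger.warning("no live replicates at station=%r depth=%r", station, depth)
            continue
        control_fraction = np.nan
        clipped = [False] * len(incs)
        if correct_with_control and len(ctrl) > 0:
            if len(ctrl) > 1:
                raise TracerError(
                    f"expected one killed control at station={station!r} depth={depth!r}, "
                    f"got {len(ctrl)}"
                )
            c = ctrl.iloc[0]
            control = TracerIncubation(
                dpm_product=float(c.dpm_product),
                dpm_total=float(c.dpm_total),
                t_days=float(c.t_days),
                is_killed_control=True,
                station=station,
                depth_m=depth,
            )
            control_fraction = control.turnover_fraction
            fractions, clipped = control_correct(incs, control)
        else:
            fractions = [i.turnover_fraction for i in incs]
        ks = np.array([f / i.t_days for f, i in zip(fractions, incs)])
        ch4 = float(np.nanmean([i.ch4_in_situ for i in incs]))
        moxs = np.array([mox_rate(k, ch4) for k in ks])
        rows.append(
            {
                "station": station,
                "depth_m": depth,
                "k_per_day": float(ks.mean()),
                "k_sd": float(ks.std(ddof=1)) if len(ks) > 1 else np.nan,
                "mox_nmol_l_d": float(moxs.mean()),
                "mox_sd": float(moxs.std(ddof=1)) if len(moxs) > 1 else np.nan,
                "ch4_nmol_l": ch4,
                "n_reps": len(ks),
                "control_fraction": control_fraction,
                "any_clipped": bool(any(clipped)),
            }
        )
    return pd.DataFrame(rows)


def replicate_stats(estimates: pd.DataFrame, by=("station", "depth_m")) -> pd.DataFrame:
    """Mean and sample sd of k and MOx for replicate-level estimate tables.

    ``estimates`` needs columns ``k_per_day`` and ``mox_nmol_l_d`` plus the
    grouping keys.  Groups with a single member pass through with sd NaN.
    """
    def agg(g: pd.DataFrame) -> pd.Series:
        return pd.Series(
            {
                "k_mean": g["k_per_day"].mean(),
                "k_sd": g["k_per_day"].std(ddof=1) if len(g) > 1 else np.nan,
                "mox_mean": g["mox_nmol_l_d"].mean(),
                "mox_sd": g["mox_nmol_l_d"].std(ddof=1) if len(g) > 1 else np.nan,
                "n_reps": len(g),
            }
        )

    out = estimates.groupby(list(by), sort=False).apply(agg, include_groups=False)
    return out.reset_index()
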