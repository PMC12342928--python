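"""Amendment-incubation analysis: net methane production and lag detection.

Microcosm incubations amended with methylated precursors (methylphosphonate,
MPn + inorganic phosphate, DMSP) are compared against an unamended control
sampled at the same times.  The quantities of interest are the net methane
accumulation over the incubation, a control-corrected linear production
rate, and the lag before production starts (e.g. MPn + Pi treatments only
produce methane once the added phosphate is drawn down).

Tables carry columns ``treatment, replicate, t_days, ch4_nmol_l``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats


class IncubationError(ValueError):
    pass


def _mean_sd_at(series: pd.DataFrame, t: float) -> tuple[float, float, int]:
    at = series[np.isclose(series["t_days"], t)]["ch4_nmol_l"]
    if at.empty:
        raise IncubationError(f"no observations at t={t} d")
    return float(at.mean()), float(at.std(ddof=1)) if len(at) > 1 else np.nan, len(at)


def _check_series(series: pd.DataFrame, name: str) -> None:
    required = {"t_days", "ch4_nmol_l"}
    if not required <= set(series.columns):
        raise IncubationError(f"{name} table needs columns {sorted(required)}")
    if series["t_days"].min() < 0:
        raise IncubationError(f"{name} has negative times")
    if series["t_days"].nunique() < 2:
        raise IncubationError(f"{name} needs at least 2 time points")


def net_accumulation(
    treatment: pd.DataFrame, control: pd.DataFrame
) -> tuple[float, float]:
    """Control-corrected net CH4 accumulation (nmol l-1) over the incubation.

    (treatment final - treatment initial) - (control final - control
    initial), replicate-averaged, with the standard deviation propagated in
    quadrature across the four replicate means.  Treatment and control must
    share the final time point.
    """
    _check_series(treatment, "treatment")
    _check_series(control, "control")
    t0, t1 = float(treatment["t_days"].min()), float(treatment["t_days"].max())
    if not np.isclose(float(control["t_days"].max()), t1):
        raise IncubationError("treatment and control must share the final time point")
    m_t1, s_t1, n_t1 = _mean_sd_at(treatment, t1)
    m_t0, s_t0, n_t0 = _mean_sd_at(treatment, t0)
    m_c1, s_c1, n_c1 = _mean_sd_at(control, float(control["t_days"].max()))
    m_c0, s_c0, n_c0 = _mean_sd_at(control, float(control["t_days"].min()))
    net = (m_t1 - m_t0) - (m_c1 - m_c0)
    terms = [
        (s / np.sqrt(n)) ** 2
        for s, n in ((s_t1, n_t1), (s_t0, n_t0), (s_c1, n_c1), (s_c0, n_c0))
        if np.isfinite(s)
    ]
    sd = float(np.sqrt(sum(terms))) if terms else np.nan
    return float(net), sd


def _control_corrected_means(
    treatment: pd.DataFrame, control: pd.DataFrame
) -> pd.DataFrame:
    """Treatment replicate means minus time-matched control means."""
    tm = treatment.groupby("t_days")["ch4_nmol_l"].mean()
    cm = control.groupby("t_days")["ch4_nmol_l"].mean()
    common = tm.index.intersection(cm.index)
    if len(common) < 2:
        raise IncubationError("treatment and control share fewer than 2 time points")
    return pd.DataFrame(
        {"t_days": common.to_numpy(), "corrected": (tm[common] - cm[common]).to_numpy()}
    )


def production_rate(
    treatment: pd.DataFrame,
    control: pd.DataFrame,
    window: tuple[float, float] | None = None,
):
    """Least-squares slope (nmol l-1 d-1) of control-corrected CH4 vs time.

    ``window`` restricts the fit to ``t0 <= t <= t1`` (e.g. after a
    detected lag).  Returns the scipy linregress result, whose ``slope`` is
    the production rate and ``stderr`` its standard error.
    """
    _check_series(treatment, "treatment")
    _check_series(control, "control")
    cc = _control_corrected_means(treatment, control)
    if window is not None:
        lo, hi = window
        cc = cc[(cc["t_days"] >= lo) & (cc["t_days"] <= hi)]
    if len(cc) < 3:
        raise IncubationError("need at least 3 time points in the fit window")
    return stats.linregress(cc["t_days"], cc["corrected"])


def detect_lag(
    treatment: pd.DataFrame,
    control: pd.DataFrame,
    threshold_sd: float = 3.0,
) -> float | None:
    """Earliest time of sustained control-corrected CH4 excess, in days.

    The detection threshold is ``threshold_sd`` times the pooled replicate
    standard deviation; the excess must persist at every later sampled time
    (a sustained-exceedance rule, robust at sparse time resolution).
    Returns None when the threshold is never sustainedly exceeded.
    """
    _check_series(treatment, "treatment")
    _check_series(control, "control")
    if treatment["t_days"].nunique() < 4:
        raise IncubationError("lag detection needs at least 4 time points")
    cc = _control_corrected_means(treatment, control).sort_values("t_days")

    # pooled within-time replicate sd across both series
    devs = []
    for df in (treatment, control):
        for _, grp in df.groupby("t_days"):
            if len(grp) > 1:
                devs.append(grp["ch4_nmol_l"] - grp["ch4_nmol_l"].mean())
    pooled_sd = float(pd.concat(devs).std(ddof=1)) if devs else 0.0
    thresh = threshold_sd * pooled_sd

    above = cc["corrected"].to_numpy() > thresh
    t = cc["t_days"].to_numpy()
    for i in range(len(t)):
        if above[i:].all() and above[i]:
            if t[i] == t[0]:
                # baseline itself exceeds: report first post-zero time
                return float(t[min(1, len(t) - 1)])
            return float(t[i])
    return None
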