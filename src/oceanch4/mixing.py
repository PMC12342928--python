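"""Conservative dilution modelling and driver attribution for dissolved CH4.

When two water masses with distinct salinity and methane content mix
conservatively, dissolved CH4 falls on a straight "theoretical dilution
line" between the endmember (S, CH4) pairs.  Departures from that line
diagnose non-conservative behaviour: samples below the line point to net
consumption (microbial oxidation, ventilation), samples above to net
production.

The module also attributes observed CH4 variability to hydrographic drivers
with an ordinary least-squares regression whose explained variance is
decomposed into per-predictor shares by averaging sequential sums of squares
over all predictor orderings (the LMG / Shapley decomposition), which is
order-independent by construction.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger(__name__)


class MixingError(ValueError):
    pass


@dataclass(frozen=True)
class DilutionModel:
    """Two-endmember conservative mixing line for CH4 against salinity."""

    s_a: float
    ch4_a: float
    s_b: float
    ch4_b: float

    def __post_init__(self) -> None:
        if self.s_a == self.s_b:
            raise MixingError("endmember salinities must differ")

    @classmethod
    def from_observations(cls, salinity, ch4) -> "DilutionModel":
        """Default endmembers: the transect salinity extremes."""
        s = np.asarray(salinity, dtype=float)
        c = np.asarray(ch4, dtype=float)
        i_min, i_max = int(np.argmin(s)), int(np.argmax(s))
        return cls(s_a=s[i_min], ch4_a=c[i_min], s_b=s[i_max], ch4_b=c[i_max])

    def predict(self, salinity, flag_extrapolation: bool = True):
        """CH4 (nmol l-1) on the dilution line at the given salinities.

        Salinities outside the closed endmember interval are extrapolated
        but logged when ``flag_extrapolation``.
        """
        s = np.asarray(salinity, dtype=float)
        lo, hi = sorted((self.s_a, self.s_b))
        if flag_extrapolation and (np.any(s < lo) or np.any(s > hi)):
            logger.warning("dilution prediction extrapolates outside [%g, %g]", lo, hi)
        frac = (s - self.s_a) / (self.s_b - self.s_a)
        out = self.ch4_a + frac * (self.ch4_b - self.ch4_a)
        return float(out) if out.ndim == 0 else out


def dilution_residuals(
    model: DilutionModel,
    salinity,
    ch4,
    latitude=None,
    lat_bands=None,
) -> tuple[np.ndarray, dict]:
    """Observed minus dilution-line CH4, with summary diagnostics.

    Returns ``(residuals, summary)`` where the summary holds the mean
    residual, the fraction of negative residuals (net-consumption
    indicator), and, when latitudes are supplied, the mean residual per
    latitude band (default 1-degree bands).
    """
    s = np.asarray(salinity, dtype=float)
    c = np.asarray(ch4, dtype=float)
    if s.size == 0:
        raise MixingError("at least one observation required")
    resid = c - model.predict(s, flag_extrapolation=False)
    summary: dict = {
        "mean_residual": float(resid.mean()),
        "sd_residual": float(resid.std(ddof=1)) if resid.size > 1 else np.nan,
        "frac_negative": float(np.mean(resid < 0)),
        "n": int(resid.size),
    }
    if latitude is not None:
        lat = np.asarray(latitude, dtype=float)
        if lat_bands is None:
            lat_bands = np.arange(np.floor(lat.min()), np.ceil(lat.max()) + 1.0)
        banded = (
            pd.DataFrame({"lat": lat, "resid": resid})
            .assign(band=lambda d: pd.cut(d["lat"], bins=lat_bands))
            .groupby("band", observed=True)["resid"]
            .mean()
        )
        summary["mean_residual_by_band"] = banded
    return resid, summary


def _shapley_r2(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, float]:
    """Shapley (LMG) decomposition of R^2 over predictors.

    Computes R^2 for every predictor subset and averages the sequential
    increment of each predictor over all orderings.  Exact; exponential in
    p, intended for the handful of hydrographic drivers used here.
    """
    n, p = X.shape
    subset_r2: dict[frozenset, float] = {frozenset(): 0.0}
    for r in range(1, p + 1):
        for combo in itertools.combinations(range(p), r):
            Xc = sm.add_constant(X[:, combo])
            subset_r2[frozenset(combo)] = float(sm.OLS(y, Xc).fit().rsquared)
    shapley = np.zeros(p)
    orders = list(itertools.permutations(range(p)))
    for order in orders:
        seen: set[int] = set()
        for j in order:
            before = subset_r2[frozenset(seen)]
            seen.add(j)
            after = subset_r2[frozenset(seen)]
            shapley[j] += after - before
    shapley /= len(orders)
    return shapley, subset_r2[frozenset(range(p))]


@dataclass
class DriverAttribution:
    """OLS fit of CH4 on hydrographic drivers with variance shares."""

    adjusted_r2: float
    r2: float
    shares_pct: pd.Series  # per-predictor % of total variability
    coefficients: pd.DataFrame  # coef, std err, t, p per predictor
    condition_number: float
    collinear: bool


def driver_regression(
    response,
    predictors: pd.DataFrame,
    condition_threshold: float = 1e3,
) -> DriverAttribution:
    """Attribute response variability to predictors by OLS + LMG shares.

    Predictors are standardized internally (zero mean, unit variance).  The
    per-predictor shares are Shapley-decomposed R^2 contributions expressed
    as a percentage of total variability, so they sum to 100 * R^2 <= 100.
    Severe collinearity is flagged but shares are still computed (the
    Shapley decomposition remains well defined).
    """
    y = np.asarray(response, dtype=float)
    X_raw = predictors.to_numpy(dtype=float)
    n, p = X_raw.shape
    if n <= p + 2:
        raise MixingError(f"need n > p + 2 observations (n={n}, p={p})")
    sd = X_raw.std(axis=0, ddof=0)
    if np.any(sd == 0):
        bad = list(predictors.columns[sd == 0])
        raise MixingError(f"constant predictors: {bad}")
    X = (X_raw - X_raw.mean(axis=0)) / sd

    fit = sm.OLS(y, sm.add_constant(X)).fit()
    cond = float(np.linalg.cond(X))
    collinear = cond > condition_threshold
    if collinear:
        logger.warning("predictor condition number %.3g exceeds threshold", cond)

    shapley, r2 = _shapley_r2(y, X)
    shares = pd.Series(shapley * 100.0, index=list(predictors.columns)).clip(lower=0.0)

    coeffs = pd.DataFrame(
        {
            "coef": fit.params[1:],
            "std_err": fit.bse[1:],
            "t": fit.tvalues[1:],
            "p_value": fit.pvalues[1:],
        },
        index=list(predictors.columns),
    )
    return DriverAttribution(
        adjusted_r2=float(fit.rsquared_adj),
        r2=float(r2),
        shares_pct=shares,
        coefficients=coeffs,
        condition_number=cond,
        collinear=collinear,
    )


def correlations(table: pd.DataFrame, pairs: list[tuple[str, str]]) -> pd.DataFrame:
    """Pearson r and two-sided p for column pairs, pairwise-complete."""
    rows = []
    for a, b in pairs:
        sub = table[[a, b]].dropna()
        if len(sub) < 3:
            raise MixingError(f"pair ({a}, {b}) has fewer than 3 complete observations")
        r, p = stats.pearsonr(sub[a], sub[b])
        rows.append({"x": a, "y": b, "r": float(r), "p_value": float(p), "n": len(sub)})
    return pd.DataFrame(rows)
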