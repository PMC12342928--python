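"""Optimum multiparameter (OMP) water-mass analysis.

OMP analysis treats each seawater sample as a linear mixture of a small set
of predefined endmember water masses, each characterized by six conservative
(or quasi-conservative) properties: potential temperature T, salinity S,
dissolved oxygen O, phosphate P, nitrate N, and silicate Si.  For mixing
fractions ``x_i`` the property-conservation system is::

    sum_i x_i * T_i  = T_obs  + R_T
    sum_i x_i * S_i  = S_obs  + R_S
    ...                               (one row per property)
    sum_i x_i        = 1      + R_M   (mass conservation)

subject to ``x_i >= 0``.  Because the six properties have incommensurate
units, each property row is standardized by the across-endmember spread of
that property and multiplied by a user weight before the weighted
least-squares solve; mass conservation enters as a heavily weighted soft
constraint so ``R_M`` is reported rather than forced to zero.  The
non-negative solution is found with Lawson–Hanson NNLS.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls

logger = logging.getLogger(__name__)

#: Canonical property order used throughout the package.
PROPERTIES = ("T", "S", "O", "P", "N", "Si")

#: Default ratio of the mass-conservation weight to the property weights.
DEFAULT_MASS_WEIGHT = 100.0


class OMPError(ValueError):
    """Raised for unsolvable or invalid OMP inputs."""


@dataclass(frozen=True)
class EndmemberSet:
    """Named water-mass endmembers with their six defining properties.

    Parameters
    ----------
    names
        Water-mass labels, e.g. ``["Kuroshio", "Oyashio"]``.
    properties
        Array of shape ``(n_endmembers, 6)`` in the order
        T (degC), S, O (umol/l), P (umol/l), N (umol/l), Si (umol/l).
    property_weights
        Non-negative weight per property (length 6).  Defaults to uniform.
    mass_weight
        Weight of the mass-conservation row relative to a unit property
        weight.  Large values make ``sum(x)`` adhere closely to 1 while
        still reporting the residual ``R_M``.
    """

    names: tuple[str, ...]
    properties: np.ndarray
    property_weights: np.ndarray = field(default=None)  # type: ignore[assignment]
    mass_weight: float = DEFAULT_MASS_WEIGHT

    def __post_init__(self) -> None:
        props = np.asarray(self.properties, dtype=float)
        object.__setattr__(self, "names", tuple(self.names))
        object.__setattr__(self, "properties", props)
        if props.ndim != 2 or props.shape[1] != len(PROPERTIES):
            raise OMPError(
                f"properties must be (n_endmembers, {len(PROPERTIES)}); got {props.shape}"
            )
        n = props.shape[0]
        if len(self.names) != n:
            raise OMPError("names and properties disagree on endmember count")
        if n < 2:
            raise OMPError("at least 2 endmembers are required")
        if n > 7:
            raise OMPError(
                "at most 7 endmembers supported (6 properties + mass row)"
            )
        if not np.all(np.isfinite(props)):
            raise OMPError("endmember properties contain non-finite values")
        for i in range(n):
            for j in range(i + 1, n):
                if np.allclose(props[i], props[j]):
                    raise OMPError(
                        f"endmembers {self.names[i]!r} and {self.names[j]!r} "
                        "are identical in all six properties"
                    )
        if self.property_weights is None:
            w = np.ones(len(PROPERTIES))
        else:
            w = np.asarray(self.property_weights, dtype=float)
        if w.shape != (len(PROPERTIES),) or np.any(w < 0):
            raise OMPError("property_weights must be 6 non-negative numbers")
        object.__setattr__(self, "property_weights", w)
        if self.mass_weight <= 0:
            raise OMPError("mass_weight must be positive")

    @property
    def n_endmembers(self) -> int:
        return self.properties.shape[0]

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        mass_weight: float = DEFAULT_MASS_WEIGHT,
    ) -> "EndmemberSet":
        """Build from a table with columns name, T, S, O, P, N, Si[, weight].

        A ``weight`` column, if present, is interpreted per *property* only
        when the table is transposed by the caller; per-row weights are not
        part of the model and are ignored with a warning.
        """
        missing = [c for c in ("name", *PROPERTIES) if c not in df.columns]
        if missing:
            raise OMPError(f"endmember table missing columns: {missing}")
        if "weight" in df.columns:
            logger.warning("per-endmember 'weight' column ignored; weights are per property")
        return cls(
            names=tuple(str(x) for x in df["name"]),
            properties=df[list(PROPERTIES)].to_numpy(dtype=float),
            mass_weight=mass_weight,
        )


@dataclass
class OMPSolution:
    """Result of a per-sample OMP inversion."""

    names: tuple[str, ...]
    fractions: np.ndarray  # x_i, dimensionless
    residuals: dict[str, float]  # native units, predicted - observed
    residuals_scaled: dict[str, float]
    mass_residual: float  # sum(x) - 1
    objective: float  # weighted SSR in scaled units (incl. mass row)
    excluded_properties: tuple[str, ...] = ()
    low_confidence: bool = False
    station: object = None
    depth: float = np.nan

    @property
    def total(self) -> float:
        return float(self.fractions.sum())


@dataclass
class NormalizedSystem:
    """Scaled OMP design matrix with bookkeeping to undo the scaling."""

    matrix: np.ndarray  # (n_rows, n_endmembers); property rows then mass row
    row_properties: tuple[str, ...]  # which property each row encodes
    scales: np.ndarray  # divisor applied to each property row
    weights: np.ndarray  # multiplicative weight applied to each property row
    mass_weight: float
    excluded: tuple[str, ...]

    def scale_observations(self, obs: np.ndarray) -> np.ndarray:
        """Apply the same scaling to a vector of six observed properties."""
        idx = [PROPERTIES.index(p) for p in self.row_properties]
        b = obs[idx] / self.scales * self.weights
        return np.append(b, self.mass_weight * 1.0)


def normalize_system(endmembers: EndmemberSet) -> NormalizedSystem:
    """Standardize the property-conservation system for a weighted solve.

    Each property row is divided by the population standard deviation of
    that property across the endmember values (divisor ``n``), then
    multiplied by its property weight.  The mass-conservation row of ones is
    scaled by ``mass_weight``.  Properties with zero across-endmember spread
    carry no mixing information and are excluded with a warning.
    """
    rows = []
    row_props: list[str] = []
    scales: list[float] = []
    weights: list[float] = []
    excluded: list[str] = []
    for j, prop in enumerate(PROPERTIES):
        col = endmembers.properties[:, j]
        sd = float(np.std(col))  # population convention
        w = float(endmembers.property_weights[j])
        if sd == 0.0 or w == 0.0:
            if sd == 0.0:
                logger.warning(
                    "property %s constant across endmembers; excluded from OMP", prop
                )
            excluded.append(prop)
            continue
        rows.append(col / sd * w)
        row_props.append(prop)
        scales.append(sd)
        weights.append(w)
    if not rows:
        raise OMPError("all properties excluded; system is unsolvable")
    matrix = np.vstack(rows + [np.full(endmembers.n_endmembers, endmembers.mass_weight)])
    return NormalizedSystem(
        matrix=matrix,
        row_properties=tuple(row_props),
        scales=np.array(scales),
        weights=np.array(weights),
        mass_weight=endmembers.mass_weight,
        excluded=tuple(excluded),
    )


def _as_property_vector(sample) -> np.ndarray:
    """Extract the six observed properties from a mapping/Series/array."""
    if isinstance(sample, (pd.Series, dict)):
        try:
            vec = np.array([float(sample[p]) for p in PROPERTIES])
        except KeyError as e:
            raise OMPError(f"sample missing property {e}") from None
    else:
        vec = np.asarray(sample, dtype=float)
        if vec.shape != (len(PROPERTIES),):
            raise OMPError("sample must supply exactly six properties T,S,O,P,N,Si")
    return vec


def solve_omp(
    sample,
    endmembers: EndmemberSet,
    system: NormalizedSystem | None = None,
    residual_threshold: dict[str, float] | float | None = None,
    station=None,
    depth: float = np.nan,
) -> OMPSolution:
    """Solve one sample for non-negative water-mass mixing fractions.

    Parameters
    ----------
    sample
        Mapping/Series with keys T, S, O, P, N, Si, or a length-6 array in
        that order (native units).
    endmembers
        The endmember definitions.
    system
        Pre-computed :func:`normalize_system` output (recomputed if None).
    residual_threshold
        Optional per-property (or scalar) native-unit residual magnitude
        above which the solution is flagged low-confidence.  Flagging only;
        the solution is always returned.

    Returns
    -------
    OMPSolution with fractions ``x_i >= 0``, native-unit residuals
    (predicted minus observed), the mass residual ``sum(x) - 1``, and the
    weighted scaled objective actually minimized.
    """
    obs = _as_property_vector(sample)
    if not np.all(np.isfinite(obs)):
        raise OMPError(
            f"sample has missing/non-finite properties (station={station!r}, depth={depth!r})"
        )
    if system is None:
        system = normalize_system(endmembers)
    b = system.scale_observations(obs)
    x, rnorm = nnls(system.matrix, b)
    objective = float(rnorm**2)

    residuals: dict[str, float] = {}
    residuals_scaled: dict[str, float] = {}
    for prop in PROPERTIES:
        j = PROPERTIES.index(prop)
        pred = float(endmembers.properties[:, j] @ x)
        r = pred - obs[j]
        residuals[prop] = r
        if prop in system.row_properties:
            i = system.row_properties.index(prop)
            residuals_scaled[prop] = r / system.scales[i] * system.weights[i]
        else:
            residuals_scaled[prop] = np.nan
    mass_residual = float(x.sum() - 1.0)

    low = False
    if residual_threshold is not None:
        if np.isscalar(residual_threshold):
            thr = {p: float(residual_threshold) for p in system.row_properties}
        else:
            thr = residual_threshold  # type: ignore[assignment]
        low = any(
            abs(residuals[p]) > thr[p] for p in system.row_properties if p in thr
        )

    return OMPSolution(
        names=endmembers.names,
        fractions=x,
        residuals=residuals,
        residuals_scaled=residuals_scaled,
        mass_residual=mass_residual,
        objective=objective,
        excluded_properties=system.excluded,
        low_confidence=low,
        station=station,
        depth=depth,
    )


def omp_section(
    samples: pd.DataFrame,
    endmembers: EndmemberSet,
    residual_threshold: dict[str, float] | float | None = None,
) -> pd.DataFrame:
    """Run :func:`solve_omp` over a section table.

    ``samples`` needs columns T, S, O, P, N, Si and optionally ``station``
    and ``depth_m``.  Per-sample failures (e.g. missing values) are returned
    as flagged rows with NaN fractions rather than aborting the section.

    Returns a table with one row per sample: fraction columns named
    ``frac_<watermass>``, native-unit residual columns ``R_<prop>``,
    ``R_mass``, ``objective``, ``dominant_mass`` and flags.
    """
    if samples.empty:
        cols = (
            ["station", "depth_m"]
            + [f"frac_{n}" for n in endmembers.names]
            + [f"R_{p}" for p in PROPERTIES]
            + ["R_mass", "objective", "dominant_mass", "low_confidence", "failed"]
        )
        return pd.DataFrame(columns=cols)
    system = normalize_system(endmembers)
    records = []
    for _, row in samples.iterrows():
        station = row.get("station")
        depth = float(row.get("depth_m", np.nan))
        rec: dict = {"station": station, "depth_m": depth}
        try:
            sol = solve_omp(
                row,
                endmembers,
                system=system,
                residual_threshold=residual_threshold,
                station=station,
                depth=depth,
            )
        except OMPError as e:
            logger.warning("OMP failed for station=%r depth=%r: %s", station, depth, e)
            rec.update({f"frac_{n}": np.nan for n in endmembers.names})
            rec.update({f"R_{p}": np.nan for p in PROPERTIES})
            rec.update(
                {
                    "R_mass": np.nan,
                    "objective": np.nan,
                    "dominant_mass": None,
                    "low_confidence": True,
                    "failed": True,
                }
            )
            records.append(rec)
            continue
        rec.update({f"frac_{n}": x for n, x in zip(sol.names, sol.fractions)})
        rec.update({f"R_{p}": sol.residuals[p] for p in PROPERTIES})
        label, _, tie = classify_dominant_mass(sol)
        rec.update(
            {
                "R_mass": sol.mass_residual,
                "objective": sol.objective,
                "dominant_mass": label,
                "tie": tie,
                "low_confidence": sol.low_confidence,
                "failed": False,
            }
        )
        records.append(rec)
    return pd.DataFrame.from_records(records)


def section_summary(section: pd.DataFrame, names: tuple[str, ...]) -> pd.DataFrame:
    """Mean mixing fraction per water mass per station for a section table."""
    cols = [f"frac_{n}" for n in names]
    return section.groupby("station", dropna=False)[cols].mean()


def classify_dominant_mass(solution: OMPSolution) -> tuple[str, float, bool]:
    """Label of the largest mixing fraction.

    Ties are broken by endmember order (first wins) and flagged.

    Returns ``(label, winning_fraction, tie_flag)``.
    """
    x = solution.fractions
    i = int(np.argmax(x))
    tie = bool(np.sum(np.isclose(x, x[i])) > 1)
    if tie:
        logger.info("dominant-mass tie at station=%r; first label wins", solution.station)
    return solution.names[i], float(x[i]), tie


def grid_search_omp(
    sample,
    endmembers: EndmemberSet,
    step: float = 0.01,
) -> tuple[np.ndarray, float]:
    """Brute-force simplex grid search of the OMP objective.

    Enumerates all fraction vectors with components on a ``step`` grid that
    sum exactly to 1 and returns the best (vector, scaled weighted
    objective).  Exponential in the number of endmembers; intended as an
    independent oracle for <= 3 endmembers in tests.
    """
    obs = _as_property_vector(sample)
    system = normalize_system(endmembers)
    b = system.scale_observations(obs)
    n = endmembers.n_endmembers
    m = int(round(1.0 / step))
    # integer compositions of m into n parts
    def compositions(total: int, parts: int):
        if parts == 1:
            yield (total,)
            return
        for first in range(total + 1):
            for rest in compositions(total - first, parts - 1):
                yield (first, *rest)

    grid = np.array(list(compositions(m, n)), dtype=float) / m
    resid = grid @ system.matrix.T - b  # (n_grid, n_rows)
    obj = np.einsum("ij,ij->i", resid, resid)
    i = int(np.argmin(obj))
    return grid[i], float(obj[i])
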