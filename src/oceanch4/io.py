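"""Delimited-text readers/writers, pipeline configuration and orchestration.

All tables are CSV or TSV (delimiter auto-detected) with documented
headers; missing values are empty fields, never zero-filled.  Row-level
invariant violations are collected and reported together with 1-based
human row numbers, offending rows are dropped with a warning, and the rest
of the table loads.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import oceanch4
from oceanch4 import budget as budget_mod
from oceanch4 import gasex, mixing, omp, tracer

logger = logging.getLogger(__name__)


class SchemaError(ValueError):
    pass


def _tracer_row_check(df: pd.DataFrame) -> pd.Series:
    bad = pd.Series("", index=df.index, dtype=object)
    bad[df["dpm_total"] <= 0] = "dpm_total must be positive"
    bad[df["dpm_product"] < 0] = "dpm_product negative"
    bad[df["dpm_product"] > df["dpm_total"]] = "dpm_product exceeds dpm_total"
    bad[df["t_days"] <= 0] = "non-positive incubation time"
    return bad


def _stations_row_check(df: pd.DataFrame) -> pd.Series:
    bad = pd.Series("", index=df.index, dtype=object)
    bad[df["depth_m"] < 0] = "negative depth"
    return bad


def _underway_row_check(df: pd.DataFrame) -> pd.Series:
    bad = pd.Series("", index=df.index, dtype=object)
    bad[df["T_eq_K"] <= 0] = "non-positive equilibrator temperature"
    bad[(df["xH2O"] < 0) | (df["xH2O"] >= 1)] = "xH2O outside [0, 1)"
    bad[df["u_m_s"] < 0] = "negative wind speed"
    return bad


#: schema name -> (required columns, key columns kept as strings, row check)
SCHEMAS: dict[str, tuple[tuple[str, ...], tuple[str, ...], object]] = {
    "stations": (
        ("station", "depth_m", "T", "S", "O", "P", "N", "Si", "ch4_nmol_l"),
        ("station",),
        _stations_row_check,
    ),
    "endmembers": (("name", "T", "S", "O", "P", "N", "Si"), ("name",), None),
    "tracer": (
        (
            "station",
            "depth_m",
            "replicate",
            "is_control",
            "dpm_product",
            "dpm_total",
            "t_days",
            "ch4_nmol_l",
        ),
        ("station", "replicate"),
        _tracer_row_check,
    ),
    "underway": (
        (
            "time",
            "lat",
            "lon",
            "SST_c",
            "S",
            "xCO2_umol_mol",
            "xH2O",
            "P_eq_atm",
            "T_eq_K",
            "u_m_s",
            "ch4_water_nmol_l",
            "ch4_atm_ppb",
            "pco2_atm_uatm",
        ),
        (),
        _underway_row_check,
    ),
    "amendment": (
        ("treatment", "replicate", "t_days", "ch4_nmol_l"),
        ("treatment", "replicate"),
        None,
    ),
    "mox_profiles": (("station", "depth_m", "mox_nmol_l_d"), ("station",), None),
    "fluxes": (("station", "F_CH4_mmol_m2_y"), ("station",), None),
}


def _sniff_delimiter(path: Path) -> str:
    with open(path) as fh:
        first = fh.readline()
    return "\t" if first.count("\t") > first.count(",") else ","


def read_table(path, schema: str) -> pd.DataFrame:
    """Read and validate a delimited-text table against a named schema.

    Missing required columns raise :class:`SchemaError` listing what was
    expected.  Rows violating physical invariants are dropped together with
    a single warning naming each offending (1-based, header-exclusive) row.
    An empty file yields an empty, correctly typed table with a warning.
    """
    if schema not in SCHEMAS:
        raise SchemaError(f"unknown schema {schema!r}; known: {sorted(SCHEMAS)}")
    required, keys, row_check = SCHEMAS[schema]
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        logger.warning("%s is empty; returning empty %s table", path, schema)
        return pd.DataFrame(columns=list(required))
    df = pd.read_csv(path, sep=_sniff_delimiter(path), dtype={k: str for k in keys})
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path} does not match the {schema!r} schema: missing columns "
            f"{missing}; expected {list(required)}"
        )
    if df.empty:
        logger.warning("%s has headers but no rows", path)
        return df
    if "is_control" in df.columns:
        df["is_control"] = (
            df["is_control"].astype(str).str.strip().str.lower().isin(("1", "true", "yes"))
        )
    if row_check is not None:
        reasons = row_check(df)
        bad = reasons != ""
        if bad.any():
            msgs = [
                f"row {i + 2}: {reasons[i]}" for i in df.index[bad]
            ]  # +2: header + 1-based
            logger.warning(
                "%s: dropped %d invalid row(s):\n  %s", path, bad.sum(), "\n  ".join(msgs)
            )
            df = df[~bad].reset_index(drop=True)
    return df


def write_table(df: pd.DataFrame, path) -> Path:
    """Write a table as CSV with empty fields for missing values."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, na_rep="")
    return path


@dataclass
class PipelineConfig:
    """Paths and settings for the end-to-end analysis chain."""

    stations_path: str
    endmembers_path: str
    tracer_path: str
    underway_path: str
    output_dir: str
    fluxes_path: str | None = None  # per-station fluxes; else underway mean
    mass_weight: float = 100.0
    integration_depth_m: float = 300.0
    correct_with_control: bool = True
    seed: int = 0

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        """Load from a flat key-value (YAML-compatible) file."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        for name in ("stations_path", "endmembers_path", "tracer_path", "underway_path"):
            p = getattr(cfg, name)
            if not Path(p).exists():
                raise SchemaError(f"{name} does not exist: {p}")
        if cfg.integration_depth_m <= 0 or cfg.mass_weight <= 0:
            raise SchemaError("integration_depth_m and mass_weight must be positive")
        return cfg


def run_pipeline(config: PipelineConfig) -> dict:
    """Run OMP -> tracer kinetics -> gas exchange -> dilution -> budget.

    Each stage writes its result table under ``config.output_dir`` along
    with a machine-readable run manifest.  A stage failure raises with the
    stage name.  Returns the manifest dict.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": oceanch4.__version__,
        "config": asdict(config),
        "stages": {},
    }

    def stage(name: str, fn):
        try:
            result = fn()
        except Exception as e:
            raise RuntimeError(f"pipeline stage {name!r} failed: {e}") from e
        manifest["stages"][name] = {"rows": int(len(result))}
        return result

    endmember_table = read_table(config.endmembers_path, "endmembers")
    ems = omp.EndmemberSet.from_dataframe(endmember_table, mass_weight=config.mass_weight)

    stations = read_table(config.stations_path, "stations")
    omp_result = stage("omp", lambda: omp.omp_section(stations, ems))
    write_table(omp_result, out / "omp.csv")

    tracer_table = read_table(config.tracer_path, "tracer")
    mox_result = stage(
        "mox",
        lambda: tracer.estimate_mox(tracer_table, correct_with_control=config.correct_with_control),
    )
    write_table(mox_result, out / "mox.csv")

    underway = read_table(config.underway_path, "underway")
    flux_result = stage("flux", lambda: gasex.process_underway(underway))
    write_table(flux_result, out / "fluxes_underway.csv")

    def _dilution():
        model = mixing.DilutionModel.from_observations(
            underway["S"], underway["ch4_water_nmol_l"]
        )
        resid, summary = mixing.dilution_residuals(
            model,
            underway["S"],
            underway["ch4_water_nmol_l"],
            latitude=underway["lat"] if "lat" in underway.columns else None,
        )
        table = underway[[c for c in ("lat", "S", "ch4_water_nmol_l") if c in underway]].copy()
        table["dilution_residual_nmol_l"] = resid
        manifest["dilution_summary"] = {
            k: (float(v) if np.isscalar(v) else None) for k, v in summary.items()
        }
        return table

    dilution_result = stage("dilution", _dilution)
    write_table(dilution_result, out / "dilution.csv")

    def _budget():
        profiles = mox_result.rename(columns={"mox_nmol_l_d": "mox_nmol_l_d"})[
            ["station", "depth_m", "mox_nmol_l_d"]
        ]
        if config.fluxes_path:
            fluxes = read_table(config.fluxes_path, "fluxes")
        else:
            # no per-station flux table: apply the underway mean flux to all
            mean_flux = float(flux_result["F_CH4_mmol_m2_y"].mean())
            fluxes = pd.DataFrame(
                {"station": profiles["station"].unique(), "F_CH4_mmol_m2_y": mean_flux}
            )
        return budget_mod.station_budgets(profiles, fluxes, z_max=config.integration_depth_m)

    budget_result = stage("budget", _budget)
    write_table(budget_result, out / "budget.csv")
    if not budget_result.empty:
        summary = budget_mod.regional_summary(budget_result)
        write_table(summary, out / "budget_summary.csv")

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
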