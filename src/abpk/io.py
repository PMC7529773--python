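"""CSV dialects and run configuration.

All column headers carry units (``time_day``, ``conc_ug_per_mL``, ...)
so a file is self-describing and unit mix-ups fail loudly at parse time.
Times are stored in days, matching the 1/day rate-constant convention.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Mapping, Sequence, Union

import numpy as np
import pandas as pd

from .fitting import OneSiteBindingParams
from .quantities import (
    ConcentrationTimeProfile,
    FitResult,
    HillParams,
    MichaelisMentenParams,
    ScalingContext,
    TwoCompartmentParams,
    UptakeDataset,
    VmaxScale,
)

__all__ = [
    "ParseError",
    "RunConfig",
    "load_config",
    "read_profile_csv",
    "write_profile_csv",
    "read_uptake_csv",
    "write_uptake_csv",
    "write_params_csv",
    "PROFILE_COLUMNS",
    "UPTAKE_COLUMNS",
]

PROFILE_COLUMNS = ("animal_id", "dose_mg_per_kg", "time_day", "conc_ug_per_mL")
UPTAKE_COLUMNS = ("conc_nM", "velocity_pmol_per_min_per_5e5cells", "replicate")

TIME_FACTORS_TO_DAY = {"day": 1.0, "h": 1 / 24.0, "min": 1 / 1440.0}


class ParseError(ValueError):
    """Malformed input file; the message names the offending columns/rows."""


@dataclass(frozen=True)
class RunConfig:
    """Resolved run configuration (scaling constants, fit and solver options)."""

    n_cells_assay: float = 5e5
    n_cells_liver: float = 7.6e6
    molar_mass_g_per_mol: float = 148_000.0
    body_weight_kg: float = 0.020
    expression_ratio: float = 1.0
    weighting: str = "reciprocal_observed"
    n_random_starts: int = 5
    seed: int = 0
    ode_rtol: float = 1e-8
    ode_atol: float = 1e-10
    schema_version: int = 1

    def scaling_context(self) -> ScalingContext:
        return ScalingContext(
            n_cells_assay=self.n_cells_assay,
            n_cells_liver=self.n_cells_liver,
            molar_mass=self.molar_mass_g_per_mol,
            body_weight_kg=self.body_weight_kg,
            expression_ratio=self.expression_ratio,
        )


def load_config(path: Union[str, Path]) -> RunConfig:
    """Load a JSON run configuration; unknown keys are rejected."""
    path = Path(path)
    try:
        raw = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: not valid JSON ({exc})") from exc
    if not isinstance(raw, dict):
        raise ParseError(f"{path}: config must be a JSON object")
    known = {f.name for f in fields(RunConfig)}
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ParseError(f"{path}: unknown config keys: {', '.join(unknown)}")
    cfg = RunConfig(**raw)
    if cfg.weighting not in ("reciprocal_observed", "uniform"):
        raise ParseError(f"{path}: weighting must be reciprocal_observed or uniform")
    return cfg


def _check_columns(df: pd.DataFrame, required: Sequence[str], path: Path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(
            f"{path}: missing required columns: {', '.join(missing)} "
            f"(found: {', '.join(df.columns)})"
        )


def _check_numeric(df: pd.DataFrame, columns: Sequence[str], path: Path) -> pd.DataFrame:
    for col in columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()].tolist()
        if bad:
            rows = ", ".join(str(i + 2) for i in bad[:5])  # +2: header + 1-based
            raise ParseError(f"{path}: non-numeric values in column {col!r} at line(s) {rows}")
        df[col] = coerced
    return df


def read_profile_csv(
    path: Union[str, Path], time_unit: str = "day"
) -> dict[float, list[ConcentrationTimeProfile]]:
    """Read per-animal concentration-time data grouped by dose.

    Returns a mapping dose -> list of per-animal profiles.  ``time_unit``
    converts an input written in minutes or hours to days on read.
    """
    path = Path(path)
    if time_unit not in TIME_FACTORS_TO_DAY:
        raise ValueError(f"time_unit must be one of {sorted(TIME_FACTORS_TO_DAY)}")
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: file is empty") from exc
    _check_columns(df, PROFILE_COLUMNS, path)
    if len(df) == 0:
        raise ParseError(f"{path}: no data rows")
    df = _check_numeric(df, ["dose_mg_per_kg", "time_day", "conc_ug_per_mL"], path)
    df["time_day"] *= TIME_FACTORS_TO_DAY[time_unit]
    study: dict[float, list[ConcentrationTimeProfile]] = {}
    for (dose, _animal), grp in df.groupby(["dose_mg_per_kg", "animal_id"], sort=True):
        grp = grp.sort_values("time_day")
        profile = ConcentrationTimeProfile(
            float(dose),
            grp["time_day"].to_numpy(),
            grp["conc_ug_per_mL"].to_numpy(),
            n_animals=1,
        )
        study.setdefault(float(dose), []).append(profile)
    return study


def write_profile_csv(
    study: Mapping[float, Sequence[ConcentrationTimeProfile]], path: Union[str, Path]
) -> None:
    rows = []
    for dose in sorted(study):
        for animal_id, prof in enumerate(study[dose], start=1):
            for t, c in zip(prof.times, prof.concentrations):
                rows.append(
                    {
                        "animal_id": animal_id,
                        "dose_mg_per_kg": dose,
                        "time_day": t,
                        "conc_ug_per_mL": c,
                    }
                )
    pd.DataFrame(rows, columns=PROFILE_COLUMNS).to_csv(path, index=False, float_format="%.17g")


def read_uptake_csv(path: Union[str, Path]) -> UptakeDataset:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: file is empty") from exc
    _check_columns(df, UPTAKE_COLUMNS, path)
    if len(df) == 0:
        raise ParseError(f"{path}: no data rows")
    df = _check_numeric(df, list(UPTAKE_COLUMNS), path)
    return UptakeDataset(
        df["conc_nM"].to_numpy(),
        df["velocity_pmol_per_min_per_5e5cells"].to_numpy(),
        df["replicate"].to_numpy(),
    )


def write_uptake_csv(data: UptakeDataset, path: Union[str, Path]) -> None:
    reps = data.replicates if data.replicates is not None else np.zeros(len(data), dtype=int)
    pd.DataFrame(
        {
            "conc_nM": data.concentrations_nM,
            "velocity_pmol_per_min_per_5e5cells": data.velocities,
            "replicate": reps,
        }
    ).to_csv(path, index=False, float_format="%.17g")


_PARAM_ROWS = {
    TwoCompartmentParams: [
        ("V1", "mL/kg", lambda p: p.V1),
        ("k10", "1/day", lambda p: p.k10),
        ("k12", "1/day", lambda p: p.k12),
        ("k21", "1/day", lambda p: p.k21),
    ],
}


def _mm_unit(scale: VmaxScale) -> str:
    return "pmol/min/5e5 cells" if scale is VmaxScale.PER_ASSAY_CELLS else "ug/day/kg"


def write_params_csv(result: FitResult, path: Union[str, Path]) -> None:
    """Write a fitted parameter table (Parameter, Unit, Mean, CV%)."""
    est = result.estimates
    if isinstance(est, TwoCompartmentParams):
        rows = [(n, u, f(est)) for n, u, f in _PARAM_ROWS[TwoCompartmentParams]]
    elif isinstance(est, MichaelisMentenParams):
        rows = [("Km", "nM", est.km_nM), ("Vmax", _mm_unit(est.vmax_scale), est.vmax)]
    elif isinstance(est, HillParams):
        rows = [
            ("Km", "nM", est.km_nM),
            ("Vmax", _mm_unit(est.vmax_scale), est.vmax),
            ("n", "-", est.n),
        ]
    elif isinstance(est, OneSiteBindingParams):
        rows = [("KD", "nM", est.kd_nM), ("Bmax", "signal", est.bmax)]
    else:
        raise TypeError(f"no CSV layout for estimates of type {type(est).__name__}")
    pd.DataFrame(
        [
            {
                "Parameter": name,
                "Unit": unit,
                "Mean": value,
                "CV%": result.cv_percent.get(name, float("nan")),
            }
            for name, unit, value in rows
        ]
    ).to_csv(path, index=False, float_format="%.17g")


def read_params_csv(path: Union[str, Path]):
    """Read a parameter table back into the matching parameter record."""
    path = Path(path)
    df = pd.read_csv(path)
    _check_columns(df, ("Parameter", "Unit", "Mean"), path)
    values = dict(zip(df["Parameter"], df["Mean"]))
    units = dict(zip(df["Parameter"], df["Unit"]))
    if {"V1", "k10", "k12", "k21"} <= set(values):
        return TwoCompartmentParams(values["k10"], values["k12"], values["k21"], values["V1"])
    if {"Km", "Vmax"} <= set(values):
        scale = (
            VmaxScale.PER_KG
            if "kg" in str(units.get("Vmax", ""))
            else VmaxScale.PER_ASSAY_CELLS
        )
        if "n" in values:
            return HillParams(values["Km"], values["Vmax"], values["n"], scale)
        return MichaelisMentenParams(values["Km"], values["Vmax"], scale)
    raise ParseError(f"{path}: unrecognized parameter table")


def config_to_json(cfg: RunConfig) -> str:
    return json.dumps(asdict(cfg), indent=2)
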