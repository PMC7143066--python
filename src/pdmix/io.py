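"""Run-table and configuration I/O, packaged study fixtures.

Run tables travel as comma-separated text with the documented header
(``run_order, frr, tfr, frr_coded, tfr_coded, z_average_nm, pdi, zeta_mv``);
``#`` lines are comments, empty response cells are preserved as missing.
Configuration files are nested YAML.
"""

from __future__ import annotations

import hashlib
import json
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "RUN_TABLE_COLUMNS",
    "RunTableParseError",
    "load_run_table",
    "save_run_table",
    "load_study_runs",
    "study_metadata",
    "load_config",
    "sha256_of",
]

RUN_TABLE_COLUMNS = (
    "run_order", "frr", "tfr", "frr_coded", "tfr_coded",
    "z_average_nm", "pdi", "zeta_mv",
)
_REQUIRED = ("run_order", "frr", "tfr")
_FIXTURE = "pdm_liposome_runs.csv"


class RunTableParseError(ValueError):
    """A run-table file failed validation; the message names the location."""


def _validate(df: pd.DataFrame, source: str) -> pd.DataFrame:
    unknown = [c for c in df.columns if c not in RUN_TABLE_COLUMNS]
    if unknown:
        raise RunTableParseError(f"{source}: unknown columns {unknown}")
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise RunTableParseError(f"{source}: missing columns {missing}")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna() & (df[col].astype(str).str.strip() != "")
        if bad.any():
            row = int(np.nonzero(bad.to_numpy())[0][0])
            raise RunTableParseError(
                f"{source}: non-numeric value {df[col].iloc[row]!r} in "
                f"column {col!r}, data row {row + 1}"
            )
        df[col] = coerced
    return df


def load_run_table(path: str | Path) -> pd.DataFrame:
    """Read a delimited run table, validating columns and cells."""
    path = Path(path)
    df = pd.read_csv(path, comment="#", dtype=str, skip_blank_lines=True)
    df = _validate(df, path.name)
    if "run_order" in df.columns:
        df["run_order"] = df["run_order"].astype(int)
    return df


def save_run_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a run table as comma-separated text (round-trips exactly)."""
    cols = [c for c in RUN_TABLE_COLUMNS if c in table.columns]
    table[cols].to_csv(path, index=False)


def load_study_runs() -> pd.DataFrame:
    """The packaged 29-run liposome study table (9 distinct conditions)."""
    ref = resources.files("pdmix.data") / _FIXTURE
    with ref.open("r") as fh:
        df = pd.read_csv(fh, comment="#", dtype=str)
    df = _validate(df, _FIXTURE)
    df["run_order"] = df["run_order"].astype(int)
    return df


def study_metadata() -> dict:
    """Units, design parameters and transcription corrections of the fixture."""
    ref = resources.files("pdmix.data") / (_FIXTURE.replace(".csv", ".meta.json"))
    with ref.open("r") as fh:
        return json.load(fh)


def load_config(path: str | Path) -> dict:
    """Nested key-value (YAML) configuration file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    return cfg


def sha256_of(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
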