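"""Tabular I/O: CSV schemas, validated readers/writers, pipeline config.

All data streams are plain UTF-8 CSV with dot decimals and a mandatory
header; headers are matched order- and case-insensitively against the
declared schema.  Row-level parse failures are collected with their file
line numbers instead of aborting the whole read.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import NamedTuple, Optional

import numpy as np
import pandas as pd
import yaml

from .exceptions import ConfigError, SchemaError

__all__ = [
    "TableSchema",
    "SCHEMAS",
    "RowError",
    "ReadResult",
    "read_table",
    "write_table",
    "PipelineConfig",
]


@dataclass(frozen=True)
class TableSchema:
    name: str
    required: tuple[str, ...]
    optional: tuple[str, ...] = ()
    string_cols: tuple[str, ...] = ()

    @property
    def columns(self) -> tuple[str, ...]:
        return self.required + self.optional


SCHEMAS = {
    "rlc_steps": TableSchema(
        "rlc_steps",
        required=("shoot_id", "container_id", "treatment_par", "day",
                  "step_index", "actinic_par", "F", "Fm_prime"),
        optional=("Fo_prime", "Fm_dark", "Fo_dark"),
        string_cols=("shoot_id", "container_id"),
    ),
    "pigments": TableSchema(
        "pigments",
        required=("shoot_id", "a470", "a645", "a662",
                  "extract_volume_ml", "fresh_weight_g"),
        string_cols=("shoot_id",),
    ),
    "spectra": TableSchema(
        "spectra",
        required=("shoot_id", "wavelength_nm", "absorbance"),
        string_cols=("shoot_id",),
    ),
    "incubations": TableSchema(
        "incubations",
        required=("shoot_id", "phase", "time_h", "o2_umol_l", "volume_l",
                  "ps_surface_cm2", "total_surface_cm2"),
        string_cols=("shoot_id", "phase"),
    ),
    "fits": TableSchema(
        "fits",
        required=("shoot_id", "container_id", "treatment_par", "day", "af_kind",
                  "ps", "alpha", "beta", "etr_max", "ek", "sse", "converged",
                  "rejected"),
        optional=("reject_reason",),
        string_cols=("shoot_id", "container_id", "af_kind", "reject_reason"),
    ),
}


class RowError(NamedTuple):
    line: int  # 1-based file line number (header is line 1)
    column: str
    message: str


class ReadResult(NamedTuple):
    frame: pd.DataFrame
    errors: list


def read_table(path, schema: TableSchema | str) -> ReadResult:
    """Read and validate a CSV against a schema.

    Missing required columns raise :class:`SchemaError` naming the column;
    rows whose required numeric cells fail to parse are dropped and reported
    with their file line numbers.  Optional columns may be absent or empty.
    """
    if isinstance(schema, str):
        schema = SCHEMAS[schema]
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"no such file: {path}")
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    rename = {c: c.strip() for c in raw.columns}
    raw = raw.rename(columns=rename)
    lower_map = {c.lower(): c for c in raw.columns}
    missing = [c for c in schema.required if c.lower() not in lower_map]
    if missing:
        raise SchemaError(
            f"{path.name}: missing required column(s): {', '.join(missing)}"
        )
    # canonicalize header names (case-insensitive match)
    raw = raw.rename(columns={lower_map[c.lower()]: c for c in schema.columns
                              if c.lower() in lower_map})

    errors: list[RowError] = []
    out = {}
    bad_rows = np.zeros(len(raw), dtype=bool)
    for col in schema.columns:
        if col not in raw.columns:
            continue
        if col in schema.string_cols:
            out[col] = raw[col].astype(str)
            continue
        parsed = pd.to_numeric(raw[col].replace("", np.nan), errors="coerce")
        unparsed = parsed.isna() & (raw[col] != "")
        for i in np.where(unparsed)[0]:
            errors.append(RowError(int(i) + 2, col,
                                   f"unparseable value {raw[col].iloc[i]!r}"))
        if col in schema.required:
            empty = raw[col] == ""
            for i in np.where(empty)[0]:
                errors.append(RowError(int(i) + 2, col, "missing required value"))
            bad_rows |= (unparsed | empty).to_numpy()
        else:
            bad_rows |= unparsed.to_numpy()
        out[col] = parsed
    frame = pd.DataFrame(out).loc[~bad_rows].reset_index(drop=True)
    return ReadResult(frame, errors)


def write_table(frame: pd.DataFrame, path, schema: Optional[TableSchema | str] = None) -> None:
    """Write a CSV in canonical column order (UTF-8, dot decimals, header)."""
    if schema is not None:
        if isinstance(schema, str):
            schema = SCHEMAS[schema]
        cols = [c for c in schema.columns if c in frame.columns]
        frame = frame[cols]
    frame.to_csv(path, index=False)


@dataclass(frozen=True)
class PipelineConfig:
    """Run-level configuration; schema-validated, unknown keys rejected."""

    af_policy: str = "default_044"  # default_044 | af_total | af_photo
    photoperiod_h: float = 14.0
    temperature_c: float = 11.0  # metadata only
    smoothing_criterion: str = "gcv"
    seed: int = 0
    basis_dim: int = 7
    saturation_par: float = 200.0
    npp_plateau_par: float = 74.0
    qc_max_actinic: Optional[float] = None

    def __post_init__(self) -> None:
        if self.af_policy not in ("default_044", "af_total", "af_photo"):
            raise ConfigError(f"unknown AF policy {self.af_policy!r}")
        if not 0 < self.photoperiod_h <= 24:
            raise ConfigError("photoperiod must lie in (0, 24] hours")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError("config file must contain a mapping")
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)

    def content_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
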