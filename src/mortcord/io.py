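"""Delimited-table schemas and readers/writers for the pipeline.

All tables are UTF-8 CSV with a header row and ISO-8601 dates.  Registries
carry ``record_id, first_name, last_name, gender, birth_date, ssn, mrn,
death_date`` (the death-master extract has no ``mrn``); encounters carry
``record_id, source, encounter_date``; a crosswalk is two columns of record
ids; a category-count table is ``category, count``.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

import pandas as pd
import yaml

REGISTRY_COLUMNS = [
    "record_id", "first_name", "last_name", "gender", "birth_date",
    "ssn", "mrn", "death_date",
]
ENCOUNTER_COLUMNS = ["record_id", "source", "encounter_date"]

_PathLike = Union[str, Path]


class IngestError(ValueError):
    """A required input table is missing, empty, or malformed."""


def _read_csv(path: _PathLike, required: list[str], allow_missing=()) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise IngestError(f"input file not found: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if len(df) == 0:
        raise IngestError(f"empty input table: {path}")
    need = [c for c in required if c not in allow_missing]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise IngestError(f"{path}: missing columns {missing}")
    return df


def read_registry(path: _PathLike) -> pd.DataFrame:
    """Read a health-system registry or death-master extract."""
    df = _read_csv(path, REGISTRY_COLUMNS, allow_missing=("mrn", "ssn"))
    for col in ("birth_date", "death_date"):
        df[col] = pd.to_datetime(df[col].replace("", pd.NaT), format="%Y-%m-%d")
    for col in ("ssn", "mrn"):
        if col in df.columns:
            df[col] = df[col].replace("", pd.NA)
    return df


def read_encounters(path: _PathLike) -> pd.DataFrame:
    df = _read_csv(path, ENCOUNTER_COLUMNS)
    df["encounter_date"] = pd.to_datetime(df["encounter_date"], format="%Y-%m-%d")
    return df


def read_crosswalk(path: _PathLike) -> pd.DataFrame:
    return _read_csv(path, ["record_id_a", "record_id_b"])


def read_category_counts(path: _PathLike) -> dict:
    df = _read_csv(path, ["category", "count"])
    return {row.category: int(row.count) for row in df.itertuples(index=False)}


def write_table(df: pd.DataFrame, path: _PathLike) -> Path:
    """Write a table as UTF-8 CSV with ISO dates; returns the path."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = df.copy()
    for col in out.columns:
        if pd.api.types.is_datetime64_any_dtype(out[col]):
            out[col] = out[col].dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False, encoding="utf-8", lineterminator="\n")
    return path


def write_json(obj: dict, path: _PathLike) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n", encoding="utf-8")
    return path


def load_yaml(path: _PathLike) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise IngestError(f"configuration file {path} must hold a mapping")
    return data
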