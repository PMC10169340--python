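"""Readers and writers for the delimited-text extract tables.

Five tables make up an extract: demographics, visits, diagnoses, labs
(eGFR values) and procedures (hemodialysis events).  All are UTF-8 CSV with
a header row and ISO-8601 dates.  Readers validate the schema and apply
explicit dtypes; any deviation raises :class:`~temporeg.errors.DataError`.
"""
from __future__ import annotations

from pathlib import Path

import pandas as pd

from .errors import DataError

_SCHEMAS: dict[str, dict] = {
    "demographics": {
        "dtypes": {"patient_id": str, "clinic_id": str, "birth_year": int,
                   "sex": str, "ethnic_group": str, "region": str,
                   "ses_decile": int, "current_smoker": int},
        "dates": [],
    },
    "visits": {
        "dtypes": {"patient_id": str, "clinic_id": str, "provider_role": str,
                   "duration_minutes": float, "modality": str},
        "dates": ["date"],
    },
    "diagnoses": {
        "dtypes": {"patient_id": str, "code": str, "code_system": str},
        "dates": ["date"],
    },
    "labs": {
        "dtypes": {"patient_id": str, "egfr": float},
        "dates": ["date"],
    },
    "procedures": {
        "dtypes": {"patient_id": str, "procedure": str},
        "dates": ["date"],
    },
}

TABLE_NAMES = tuple(_SCHEMAS)


def read_table(path: str | Path, table: str) -> pd.DataFrame:
    """Read and validate one extract table."""
    if table not in _SCHEMAS:
        raise ValueError(f"unknown table kind: {table!r}")
    schema = _SCHEMAS[table]
    path = Path(path)
    if not path.exists():
        raise DataError(f"missing input table: {path}")
    try:
        df = pd.read_csv(path, dtype=schema["dtypes"])
    except (ValueError, pd.errors.ParserError) as exc:
        raise DataError(f"cannot parse {path}: {exc}") from exc
    expected = set(schema["dtypes"]) | set(schema["dates"])
    missing = expected - set(df.columns)
    if missing:
        raise DataError(f"{path}: missing columns {sorted(missing)}")
    for col in schema["dates"]:
        try:
            df[col] = pd.to_datetime(df[col], format="%Y-%m-%d")
        except ValueError as exc:
            raise DataError(f"{path}: bad date in column {col!r}: {exc}") from exc
    return df


def read_extract(directory: str | Path) -> dict[str, pd.DataFrame]:
    """Read all five extract tables from ``directory`` (``<name>.csv``)."""
    directory = Path(directory)
    return {name: read_table(directory / f"{name}.csv", name)
            for name in TABLE_NAMES}


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = df.copy()
    for col in out.columns:
        if pd.api.types.is_datetime64_any_dtype(out[col]):
            out[col] = out[col].dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)
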