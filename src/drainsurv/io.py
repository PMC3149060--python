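"""CSV schemas and round-trip readers/writers for the event tables.

All files are UTF-8 comma-separated with dot decimals.  Days are integer
offsets from the admission day (day 0); calendar year travels as a separate
column.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import pandas as pd

from .synth_cohort import RawEventTables, TABLE_NAMES

SCHEMAS: dict[str, list[str]] = {
    "patients": [
        "patient_id", "age", "sex_female", "admission_day", "discharge_day",
        "icu_days", "death_day", "preexisting_cns_infection",
        "placed_other_centre", "external_site", "year",
    ],
    "drains": ["patient_id", "drain_type", "insertion_day", "removal_day", "indication"],
    "labs": ["patient_id", "day", "analyte", "value", "unit"],
    "cultures": ["patient_id", "day", "site", "organism", "cons_flag", "positive_flag"],
    "antibiotics": ["patient_id", "agent", "start_day", "systemic_flag"],
    "outcomes": ["patient_id", "drm_flag", "infection_day"],
}

SCHEMA_VERSION = "1"


class SchemaError(ValueError):
    pass


def write_tables(tables: RawEventTables, out_dir) -> dict:
    """Write the six tables as CSV; returns {table: sha256 of file}."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    hashes = {}
    for name in TABLE_NAMES:
        path = out_dir / f"{name}.csv"
        getattr(tables, name).to_csv(path, index=False)
        hashes[name] = sha256_file(path)
    return hashes


def read_tables(in_dir) -> RawEventTables:
    """Read the six event tables, validating required columns.

    Extra columns are preserved with a warning; a missing required column is
    an error naming the column.
    """
    in_dir = Path(in_dir)
    frames = {}
    for name, required in SCHEMAS.items():
        path = in_dir / f"{name}.csv"
        if not path.exists():
            raise SchemaError(f"missing table file: {path}")
        df = pd.read_csv(path)
        absent = [c for c in required if c not in df.columns]
        if absent:
            raise SchemaError(f"table {name!r} lacks required column(s): {absent}")
        extra = [c for c in df.columns if c not in required]
        if extra:
            warnings.warn(f"table {name!r} has extra column(s) {extra}; preserved")
        frames[name] = df
    return RawEventTables(**frames)


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_report(report: dict, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, default=_json_default)


def _json_default(obj):
    import numpy as np

    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")
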