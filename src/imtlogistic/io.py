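"""Cohort file input/output.

Cohorts travel as delimited text (comma by default, tab accepted) with the
header columns

    patient_id, sex, group, statin_status, statin_drug, statin_dose_mg,
    statin_duration_months, age_years, side, imt_mm

of which ``age_years`` and ``imt_mm`` are required; unknown extra columns
are preserved and ignored.  Common aliases (``age`` for ``age_years``,
``imt``/``IMT`` for ``imt_mm``) are accepted on read.  Rows failing the
physiological screen (age in (0, 120], IMT in (0, 5) mm) are dropped with a
logged count so group sizes stay auditable.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

__all__ = ["read_dataset", "write_dataset", "SCHEMA_COLUMNS", "SchemaError"]

log = logging.getLogger(__name__)

SCHEMA_COLUMNS = [
    "patient_id",
    "sex",
    "group",
    "statin_status",
    "statin_drug",
    "statin_dose_mg",
    "statin_duration_months",
    "age_years",
    "side",
    "imt_mm",
]

REQUIRED = ["age_years", "imt_mm"]

ALIASES = {
    "age": "age_years",
    "age_y": "age_years",
    "imt": "imt_mm",
    "IMT": "imt_mm",
    "imt_mean_mm": "imt_mm",
    "id": "patient_id",
    "subject": "patient_id",
}


class SchemaError(ValueError):
    """Raised when a dataset file lacks required columns."""


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","


def read_dataset(
    path: str | Path,
    group: str | None = None,
    sex: str | None = None,
    statin_status: str | None = None,
) -> pd.DataFrame:
    """Read a cohort file, apply screens and optional composable filters.

    Filters compose with AND; e.g. ``sex="M", statin_status="none"``
    selects the non-medicated male subset.  Raises :class:`SchemaError` on
    missing required columns and ``ValueError`` when no rows survive.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), keep_default_na=False, na_values=[])
    df = df.rename(columns={k: v for k, v in ALIASES.items() if k in df.columns})
    missing = [c for c in REQUIRED if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing required column(s) {missing}; found {list(df.columns)}"
        )

    n_read = len(df)
    df["age_years"] = pd.to_numeric(df["age_years"], errors="coerce")
    df["imt_mm"] = pd.to_numeric(df["imt_mm"], errors="coerce")
    keep = (
        df["age_years"].between(0, 120, inclusive="right")
        & df["imt_mm"].gt(0)
        & df["imt_mm"].lt(5)
    )
    dropped = int(n_read - keep.sum())
    if dropped:
        log.info("%s: dropped %d row(s) failing physiological screen", path, dropped)
    df = df[keep]

    for col, value in (
        ("group", group),
        ("sex", sex),
        ("statin_status", statin_status),
    ):
        if value is not None:
            if col not in df.columns:
                raise SchemaError(f"cannot filter on missing column {col!r}")
            df = df[df[col].astype(str) == value]

    if len(df) == 0:
        raise ValueError(f"{path}: no observations remain after screening/filters")
    log.info("%s: read %d rows, kept %d after screens and filters", path, n_read, len(df))
    return df.reset_index(drop=True)


def write_dataset(data: pd.DataFrame, path: str | Path) -> None:
    """Write a cohort in the standard schema; round-trips exactly."""
    path = Path(path)
    cols = [c for c in SCHEMA_COLUMNS if c in data.columns]
    cols += [c for c in data.columns if c not in cols]
    data[cols].to_csv(path, sep=_sep_for(path), index=False)
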