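"""Readers, writers and validation for the pipeline's tabular formats.

Two input dialects are accepted for per-core cell counts:

``tallies``
    One row per core with the columns patient_id, lesion_id, lesion_type,
    treated, core_id, sample_index, n_tumor_viable, n_tumor_pos,
    n_immune_pos — the schema the synthetic generator writes and the
    natural export of a cell-detection post-processing step.
``per_cell``
    One row per detected cell, as cell-detection software exports it:
    the same identifier columns plus ``cell_class`` (Tumor / Immune /
    Stroma) and ``positive`` (PD-L1 positivity flag). Rows are aggregated
    into tallies: viable tumor cells = Tumor rows, positive tumor cells =
    positive Tumor rows, positive immune cells = positive Immune rows.

All tables are CSV, UTF-8, header row, '.' decimal separator, missing
values as empty fields.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

__all__ = ["SchemaError", "TALLY_COLUMNS", "read_core_counts", "read_patients", "write_table"]

TALLY_COLUMNS = [
    "patient_id",
    "lesion_id",
    "lesion_type",
    "treated",
    "core_id",
    "sample_index",
    "n_tumor_viable",
    "n_tumor_pos",
    "n_immune_pos",
]

PER_CELL_COLUMNS = [
    "patient_id",
    "lesion_id",
    "lesion_type",
    "treated",
    "core_id",
    "sample_index",
    "cell_class",
    "positive",
]

PATIENT_COLUMNS = ["patient_id", "os_months", "event"]


class SchemaError(ValueError):
    """Missing columns or invalid values in an input table."""


def _require_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing column(s) {missing}")


def read_core_counts(path: str | Path, dialect: str = "tallies") -> pd.DataFrame:
    """Read and validate a per-core counts table.

    Returns a tallies-schema DataFrame regardless of dialect. Row-level
    violations (negative counts, more positive than viable tumor cells)
    raise :class:`SchemaError` naming the offending core.
    """
    df = pd.read_csv(path)
    if dialect == "tallies":
        _require_columns(df, TALLY_COLUMNS, f"{path}")
        out = df[TALLY_COLUMNS].copy()
    elif dialect == "per_cell":
        _require_columns(df, PER_CELL_COLUMNS, f"{path}")
        out = _aggregate_per_cell(df)
    else:
        raise SchemaError(f"unknown dialect {dialect!r}; expected 'tallies' or 'per_cell'")
    _validate_tallies(out, str(path))
    return out


def _aggregate_per_cell(cells: pd.DataFrame) -> pd.DataFrame:
    keys = ["patient_id", "lesion_id", "lesion_type", "treated", "core_id", "sample_index"]
    known = {"Tumor", "Immune", "Stroma"}
    bad = set(cells["cell_class"].unique()) - known
    if bad:
        raise SchemaError(f"per_cell table: unknown cell_class value(s) {sorted(bad)}")
    pos = cells["positive"].astype(bool)
    tallies = (
        cells.assign(
            _tumor=(cells["cell_class"] == "Tumor").astype(int),
            _tumor_pos=((cells["cell_class"] == "Tumor") & pos).astype(int),
            _immune_pos=((cells["cell_class"] == "Immune") & pos).astype(int),
        )
        .groupby(keys, as_index=False)[["_tumor", "_tumor_pos", "_immune_pos"]]
        .sum()
        .rename(
            columns={
                "_tumor": "n_tumor_viable",
                "_tumor_pos": "n_tumor_pos",
                "_immune_pos": "n_immune_pos",
            }
        )
    )
    return tallies[TALLY_COLUMNS]


def _validate_tallies(df: pd.DataFrame, source: str) -> None:
    counts = ["n_tumor_viable", "n_tumor_pos", "n_immune_pos"]
    for col in counts + ["sample_index"]:
        if df.empty:
            df[col] = pd.to_numeric(df[col])
        if not pd.api.types.is_numeric_dtype(df[col]):
            raise SchemaError(f"{source}: column {col!r} is not numeric")
    neg = df[(df[counts] < 0).any(axis=1)]
    if not neg.empty:
        raise SchemaError(
            f"{source}: negative cell counts in core(s) {neg['core_id'].tolist()[:5]}"
        )
    if (df["sample_index"] < 1).any():
        bad = df.loc[df["sample_index"] < 1, "core_id"].tolist()[:5]
        raise SchemaError(f"{source}: sample_index < 1 in core(s) {bad}")
    over = df[df["n_tumor_pos"] > df["n_tumor_viable"]]
    if not over.empty:
        raise SchemaError(
            f"{source}: n_tumor_pos exceeds n_tumor_viable in core(s) "
            f"{over['core_id'].tolist()[:5]}"
        )
    dup = df["core_id"].duplicated()
    if dup.any():
        raise SchemaError(f"{source}: duplicate core_id(s) {df.loc[dup, 'core_id'].tolist()[:5]}")


def read_patients(path: str | Path) -> pd.DataFrame:
    """Read and validate the patient-level clinical table."""
    df = pd.read_csv(path)
    _require_columns(df, PATIENT_COLUMNS, f"{path}")
    if (df["os_months"] < 0).any():
        bad = df.loc[df["os_months"] < 0, "patient_id"].tolist()[:5]
        raise SchemaError(f"{path}: negative os_months for patient(s) {bad}")
    if df["patient_id"].duplicated().any():
        raise SchemaError(f"{path}: duplicate patient_id values")
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    """Write a CSV with the pipeline's dialect (UTF-8, header, no index)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path
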