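"""Schema-validated CSV input/output.

All tables are plain CSV (RFC-4180, UTF-8, header row, "." decimal
separator).  Each schema names its required columns and which of them are
numeric; validation errors are collected with line numbers so a malformed
file is reported in one pass.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .analytes import VALID_IDS as _VALID_ANALYTES


@dataclass(frozen=True)
class Schema:
    name: str
    required: tuple[str, ...]
    numeric: tuple[str, ...]
    analyte_column: str | None = "analyte"


SCHEMAS: dict[str, Schema] = {
    s.name: s
    for s in [
        Schema(
            "calibration",
            ("analyte", "level_ug_per_ml", "response", "day", "lab", "replicate"),
            ("level_ug_per_ml", "response"),
        ),
        Schema(
            "peaks",
            ("sample_id", "analyte", "response", "mass_mg", "volume_ml", "dilution"),
            ("response", "mass_mg", "volume_ml", "dilution"),
        ),
        Schema(
            "spiking",
            (
                "condition",
                "spike_fraction",
                "replicate",
                "analyte",
                "response",
                "added_mg_per_g",
                "mass_mg",
                "volume_ml",
                "dilution",
            ),
            ("spike_fraction", "response", "added_mg_per_g", "mass_mg", "volume_ml", "dilution"),
        ),
        Schema(
            "stability",
            ("analyte", "timepoint_h", "value_mg_per_g"),
            ("timepoint_h", "value_mg_per_g"),
        ),
        Schema(
            "interlab",
            ("lab", "material", "analyte", "day", "replicate", "value"),
            ("value",),
            analyte_column=None,  # interlab analyte ids may include class labels
        ),
        Schema(
            "precision",
            ("analyte", "day", "replicate", "value"),
            ("value",),
        ),
    ]
}


class TableValidationError(ValueError):
    """Raised when a CSV fails schema validation; carries all row errors."""

    def __init__(self, path, errors: list[str]):
        self.errors = errors
        msg = f"{path}: {len(errors)} validation error(s):\n  " + "\n  ".join(errors[:20])
        if len(errors) > 20:
            msg += f"\n  ... and {len(errors) - 20} more"
        super().__init__(msg)


def read_table(path: str | Path, schema_id: str) -> pd.DataFrame:
    """Read and validate a CSV against one of the named schemas.

    Row-level problems (non-numeric cells, unknown analyte ids) are
    collected and reported together with their line numbers.
    """
    path = Path(path)
    if schema_id not in SCHEMAS:
        raise KeyError(f"unknown schema {schema_id!r}; known: {sorted(SCHEMAS)}")
    schema = SCHEMAS[schema_id]
    if not path.exists():
        raise FileNotFoundError(path)

    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in schema.required if c not in df.columns]
    if missing:
        raise TableValidationError(path, [f"missing required column(s): {', '.join(missing)}"])

    errors: list[str] = []
    for col in schema.numeric:
        raw = df[col].str.strip()
        comma = raw.str.contains(",", regex=False)
        if comma.any():
            line = int(comma.idxmax()) + 2  # +1 header, +1 1-based
            errors.append(
                f"line {line}, column {col!r}: decimal comma detected "
                f"({raw[comma.idxmax()]!r}); this reader requires '.' as the "
                "decimal separator — re-export the file with a point decimal"
            )
            continue
        converted = pd.to_numeric(raw, errors="coerce")
        bad = converted.isna() & (raw != "")
        for idx in df.index[bad]:
            errors.append(f"line {int(idx) + 2}, column {col!r}: non-numeric value {raw[idx]!r}")
        df[col] = converted
    if schema.analyte_column and schema.analyte_column in df.columns:
        unknown = ~df[schema.analyte_column].isin(_VALID_ANALYTES)
        for idx in df.index[unknown]:
            errors.append(
                f"line {int(idx) + 2}: unknown analyte id "
                f"{df.loc[idx, schema.analyte_column]!r}"
            )
    if errors:
        raise TableValidationError(path, errors)
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    """Write a table as UTF-8 CSV with '.' decimals; returns the path."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path
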