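"""CSV/YAML readers and schema detection for the pipeline.

Three long-format input schemas are recognized by their columns:

* **Ct table** — ``gene, condition, zt, replicate, ct`` (optional
  ``efficiency``): raw qPCR cycle thresholds, quantified first;
* **expression table** — ``gene, condition, zt, replicate, level``:
  pre-normalized relative expression, fed straight to the cosinor stage;
* **peak table** — ``gene, condition, peak_label, peak_time_zt``: already
  extracted acrophases, fed straight to the classification stage.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from .timeframes import ClockTime, PeakRecord, PhotoperiodScheme

__all__ = [
    "SchemaError",
    "detect_schema",
    "read_table",
    "read_schemes",
    "peaks_from_frame",
]

_SCHEMAS = {
    "ct": {"gene", "condition", "zt", "replicate", "ct"},
    "expression": {"gene", "condition", "zt", "replicate", "level"},
    "peaks": {"gene", "condition", "peak_label", "peak_time_zt"},
}


class SchemaError(ValueError):
    """An input table does not match any known schema."""


def detect_schema(df: pd.DataFrame) -> str:
    cols = set(df.columns)
    for name in ("ct", "expression", "peaks"):  # ct wins if both present
        if _SCHEMAS[name].issubset(cols):
            return name
    raise SchemaError(
        f"columns {sorted(cols)} match no known schema; expected one of "
        + "; ".join(f"{k}: {sorted(v)}" for k, v in _SCHEMAS.items())
    )


def read_table(path: str | Path) -> tuple[pd.DataFrame, str]:
    """Read an input CSV and report its detected schema.

    Numeric columns are validated row-wise; a failure names the offending
    row numbers (1-based, excluding the header).
    """
    df = pd.read_csv(path)
    schema = detect_schema(df)
    numeric = {
        "ct": ["zt", "replicate", "ct"],
        "expression": ["zt", "replicate", "level"],
        "peaks": ["peak_time_zt"],
    }[schema]
    for col in numeric:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()] + 2
        if len(bad):
            raise SchemaError(
                f"{path}: non-numeric {col!r} at rows {bad.tolist()[:10]}"
            )
        if coerced.isna().any():
            rows = (df.index[coerced.isna()] + 2).tolist()
            raise SchemaError(f"{path}: missing {col!r} at rows {rows[:10]}")
        df[col] = coerced
    return df, schema


def read_schemes(path: str | Path) -> dict[str, PhotoperiodScheme]:
    """Read photoperiod schemes from YAML or CSV.

    YAML layout: a top-level ``schemes`` list (or a bare list) of mappings
    with keys ``label, light_hours, projected, entrainment_label``. CSV:
    the same fields as columns.
    """
    path = Path(path)
    if path.suffix.lower() in (".yaml", ".yml"):
        data = yaml.safe_load(path.read_text())
        entries = data.get("schemes", data) if isinstance(data, dict) else data
    else:
        entries = pd.read_csv(path).to_dict("records")
    schemes: dict[str, PhotoperiodScheme] = {}
    for entry in entries:
        entrainment = entry.get("entrainment_label")
        if isinstance(entrainment, float) and pd.isna(entrainment):
            entrainment = None
        scheme = PhotoperiodScheme(
            label=str(entry["label"]),
            light_hours=float(entry["light_hours"]),
            projected=bool(entry.get("projected", False)),
            entrainment_label=entrainment,
        )
        schemes[scheme.label] = scheme
    return schemes


def peaks_from_frame(
    df: pd.DataFrame, schemes: Mapping[str, PhotoperiodScheme]
) -> list[PeakRecord]:
    """Turn a peak table into records, tagging ZT vs pZT from the scheme."""
    records = []
    for row in df.itertuples(index=False):
        scheme = schemes[row.condition]
        records.append(
            PeakRecord(
                gene=row.gene,
                condition=row.condition,
                peak_time=ClockTime(float(row.peak_time_zt), scheme.frame("ZT")),
                peak_label=getattr(row, "peak_label", "primary"),
            )
        )
    return records
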