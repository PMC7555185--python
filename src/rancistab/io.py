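"""Reading and writing the package's file dialects.

* Trace CSV: columns ``time_h, conductivity_uS_cm`` plus either metadata
  columns ``sample_id, temperature_C, airflow_L_h, replicate`` or a
  sidecar JSON (``<stem>.meta.json``) carrying the same keys.
* OSI table TSV: ``temperature_C, airflow_L_h, replicate, osi_h``.
* Quality panel TSV: ``sample_id, storage_months`` + marker columns.

All files are UTF-8 with '.' decimal separators; numbers are written in
full precision (repr) so write-then-read round-trips are lossless to
float precision.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import MissingColumn, NonNumericValue, UnsortedTime
from .induction import ConductivityTrace

__all__ = [
    "read_trace_csv",
    "write_trace_csv",
    "read_osi_tsv",
    "write_osi_tsv",
    "read_panel_tsv",
    "write_panel_tsv",
]

_TRACE_COLUMNS = ("time_h", "conductivity_uS_cm")
_META_COLUMNS = ("sample_id", "temperature_C", "airflow_L_h", "replicate")


def _read_table(path: Path, sep: str, required: tuple[str, ...]) -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise MissingColumn(f"{path}: missing column(s) {missing}")
    return df


def _numeric(df: pd.DataFrame, columns: tuple[str, ...], path: Path) -> pd.DataFrame:
    for col in columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # header is line 1
            raise NonNumericValue(
                f"{path}: non-numeric value {df[col][bad.idxmax()]!r} "
                f"in column {col!r} (line {line})"
            )
        df[col] = coerced
    return df


def read_trace_csv(path: str | Path) -> ConductivityTrace:
    """Read a conductivity trace; metadata from columns or sidecar JSON."""
    path = Path(path)
    df = _read_table(path, ",", _TRACE_COLUMNS)
    df = _numeric(df, _TRACE_COLUMNS, path)
    t = df["time_h"].to_numpy(dtype=float)
    if not np.all(np.diff(t) > 0):
        i = int(np.argmax(np.diff(t) <= 0))
        raise UnsortedTime(f"{path}: time not strictly increasing at line {i + 3}")

    if all(c in df.columns for c in _META_COLUMNS):
        meta = {c: df[c].iloc[0] for c in _META_COLUMNS}
    else:
        sidecar = path.with_suffix(".meta.json")
        if not sidecar.exists():
            raise MissingColumn(
                f"{path}: metadata columns {_META_COLUMNS} absent and no "
                f"sidecar {sidecar.name} found"
            )
        meta = json.loads(sidecar.read_text())
        missing = [c for c in _META_COLUMNS if c not in meta]
        if missing:
            raise MissingColumn(f"{sidecar}: missing metadata key(s) {missing}")
    return ConductivityTrace(
        sample_id=str(meta["sample_id"]),
        temperature=float(meta["temperature_C"]),
        airflow=float(meta["airflow_L_h"]),
        replicate=int(meta["replicate"]),
        time=t,
        conductivity=df["conductivity_uS_cm"].to_numpy(dtype=float),
    )


def write_trace_csv(trace: ConductivityTrace, path: str | Path) -> None:
    """Write a trace with metadata columns (self-contained file)."""
    path = Path(path)
    df = pd.DataFrame(
        {
            "time_h": trace.time,
            "conductivity_uS_cm": trace.conductivity,
            "sample_id": trace.sample_id,
            "temperature_C": trace.temperature,
            "airflow_L_h": trace.airflow,
            "replicate": trace.replicate,
        }
    )
    df.to_csv(path, index=False, float_format="%.12g")


def read_osi_tsv(path: str | Path) -> pd.DataFrame:
    """Read a replicate-level OSI table."""
    path = Path(path)
    required = ("temperature_C", "airflow_L_h", "replicate", "osi_h")
    df = _read_table(path, "\t", required)
    return _numeric(df, required, path)


def write_osi_tsv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_panel_tsv(path: str | Path) -> pd.DataFrame:
    """Read a quality-marker panel (sample_id, storage_months + markers)."""
    path = Path(path)
    df = _read_table(path, "\t", ("sample_id", "storage_months"))
    numeric_cols = tuple(c for c in df.columns if c != "sample_id")
    return _numeric(df, numeric_cols, path)


def write_panel_tsv(panel: pd.DataFrame, path: str | Path) -> None:
    panel.to_csv(path, sep="\t", index=False, float_format="%.12g")
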