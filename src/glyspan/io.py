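"""Cohort table I/O.

The on-disk contract is delimited text (comma by default) with a header
whose column names are exactly the :class:`~glyspan.core.PatientRecord`
field names.  Optional columns may be absent; empty cells mean "absent".
Floats are written with 6 significant digits, so write -> read is the
identity up to that formatting.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable, List, Sequence

import pandas as pd

from .core import GlycemiaMetrics, PatientRecord
from .errors import DataValidationError

REQUIRED_COLUMNS = ("patient_id", "hba1c_pct", "ag_mmol_L", "rbc_lifespan_days")

COLUMNS = tuple(f.name for f in dataclasses.fields(PatientRecord))

_FLAG_COLUMNS = ("cvd_flag", "neuropathy_flag", "fundus_flag")
_STR_COLUMNS = ("patient_id", "cohort_label")


def _format_value(value) -> str:
    if value is None:
        return ""
    if isinstance(value, str):
        return value
    if isinstance(value, int):
        return str(value)
    if isinstance(value, float):
        if math.isnan(value):
            return ""
        return f"{value:.6g}"
    return str(value)


def write_cohort(records: Iterable[PatientRecord], path, sep: str = ",") -> None:
    """Write records as delimited text; deterministic for a given input."""
    rows = []
    for rec in records:
        rows.append({col: _format_value(getattr(rec, col)) for col in COLUMNS})
    frame = pd.DataFrame(rows, columns=COLUMNS)
    frame.to_csv(path, sep=sep, index=False, lineterminator="\n")


def read_cohort(path, sep: str = ",") -> List[PatientRecord]:
    """Read a cohort file, validating every row.

    Rows violating the record contract are collected and reported with
    their 1-based file line numbers in a single :class:`DataValidationError`.
    """
    frame = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise DataValidationError(f"{path}: malformed header, missing columns {missing}")
    unknown = [c for c in frame.columns if c not in COLUMNS]
    if unknown:
        raise DataValidationError(f"{path}: malformed header, unknown columns {unknown}")

    records: List[PatientRecord] = []
    row_errors: List[tuple] = []
    for idx, row in frame.iterrows():
        lineno = int(idx) + 2  # header is line 1
        kwargs = {}
        try:
            for col in frame.columns:
                cell = row[col].strip()
                if cell == "":
                    if col in REQUIRED_COLUMNS:
                        raise DataValidationError(f"required column {col!r} is empty")
                    continue
                if col in _STR_COLUMNS:
                    kwargs[col] = cell
                elif col in _FLAG_COLUMNS:
                    kwargs[col] = int(float(cell))
                else:
                    kwargs[col] = float(cell)
            records.append(PatientRecord(**kwargs))
        except (DataValidationError, ValueError) as exc:
            row_errors.append((lineno, str(exc)))
    if row_errors:
        detail = "; ".join(f"line {ln}: {msg}" for ln, msg in row_errors)
        raise DataValidationError(
            f"{path}: {len(row_errors)} invalid row(s): {detail}", row_errors=row_errors
        )
    return records


def metrics_frame(metrics: Sequence[GlycemiaMetrics]) -> pd.DataFrame:
    """Tabulate derived metrics for writing alongside a cohort."""
    return pd.DataFrame(
        {
            "patient_id": [m.patient_id for m in metrics],
            "ehba1c_pct": [m.ehba1c_pct for m in metrics],
            "hgi": [m.hgi for m in metrics],
            "group": [m.group.value for m in metrics],
            "hba1c_corrected_pct": [m.hba1c_corrected_pct for m in metrics],
        }
    )


def write_metrics(metrics: Sequence[GlycemiaMetrics], path, sep: str = ",") -> None:
    frame = metrics_frame(metrics)
    for col in ("ehba1c_pct", "hgi", "hba1c_corrected_pct"):
        frame[col] = frame[col].map(lambda v: f"{v:.6g}")
    frame.to_csv(path, sep=sep, index=False, lineterminator="\n")
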