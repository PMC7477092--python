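"""CSV readers/writers with an explicit column dialect.

Instrument exports name columns inconsistently, so the mapping from file
columns to the canonical schema is a user-supplied config (never sniffed).
Files are plain comma-separated UTF-8 with a header row and '.' decimals;
container metadata (genotype, treatment, curve mode, O2) travels in leading
``# key: value`` comment lines, which keeps a written file a valid CSV for
any reader that skips comments.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

import pandas as pd
import yaml
from pydantic import BaseModel

from .core import TRACE_COLUMNS, InductionTrace, ResponseCurve, _row_valid
from .errors import EmptyInputError, FormatError

MANDATORY = ["time_s", "A", "gs", "Ci", "Ca", "PAR"]


class ColumnDialect(BaseModel):
    """Map canonical column names to the names used in a CSV file."""

    time_s: str = "time_s"
    A: str = "A"
    gs: str = "gs"
    Ci: str = "Ci"
    Ca: str = "Ca"
    PAR: str = "PAR"
    VPD: Optional[str] = "VPD"
    O2: Optional[str] = "O2"
    F: Optional[str] = "F"
    Fm_prime: Optional[str] = "Fm_prime"
    Fo: Optional[str] = "Fo"
    Fm: Optional[str] = "Fm"

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "ColumnDialect":
        with open(path, "r", encoding="utf-8") as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def rename_map(self) -> dict:
        out = {}
        for canonical, name in self.model_dump().items():
            if name is not None:
                out[name] = canonical
        return out


def _read_csv_with_meta(path) -> tuple[pd.DataFrame, dict]:
    meta = {}
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if ":" in line:
                k, v = line.lstrip("# ").rstrip("\n").split(":", 1)
                meta[k.strip()] = v.strip()
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    return df, meta


def _apply_dialect(df: pd.DataFrame, dialect: Optional[ColumnDialect]) -> pd.DataFrame:
    dialect = dialect or ColumnDialect()
    df = df.rename(columns=dialect.rename_map())
    missing = [c for c in MANDATORY if c not in df.columns]
    if missing:
        raise FormatError(f"missing mandatory column(s): {missing}")
    return df


def _validate_rows(df: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    for c in TRACE_COLUMNS:
        if c not in df.columns:
            df[c] = float("nan")
    keep = df.apply(_row_valid, axis=1)
    report = {
        "n_rows": int(len(df)),
        "n_dropped": int((~keep).sum()),
        "n_kept": int(keep.sum()),
    }
    return df.loc[keep].reset_index(drop=True), report


def read_trace(path, dialect: Optional[ColumnDialect] = None,
               genotype: Optional[str] = None,
               treatment: Optional[str] = None) -> InductionTrace:
    """Read an induction trace CSV, dropping (and counting) invalid rows.

    The number of dropped rows is recorded in ``trace.report``. Raises
    :class:`FormatError` on a missing mandatory column and
    :class:`EmptyInputError` when no row survives validation.
    """
    df, meta = _read_csv_with_meta(path)
    df = _apply_dialect(df, dialect)
    df, report = _validate_rows(df)
    if df.empty:
        raise EmptyInputError(f"{path}: no valid rows")
    trace = InductionTrace(
        df,
        genotype=genotype if genotype is not None else meta.get("genotype", ""),
        treatment=treatment if treatment is not None else meta.get("treatment", ""),
    )
    trace.report = report
    return trace


def write_trace(trace: InductionTrace, path) -> None:
    """Write a trace as CSV with metadata comment lines.

    Numeric fields are written with Python's shortest-roundtrip float
    representation, so ``read_trace(write_trace(t)) == t`` bit-for-bit.
    """
    with open(path, "w", encoding="utf-8") as fh:
        if trace.genotype:
            fh.write(f"# genotype: {trace.genotype}\n")
        if trace.treatment:
            fh.write(f"# treatment: {trace.treatment}\n")
        trace.data.to_csv(fh, index=False)


def read_curve(path, dialect: Optional[ColumnDialect] = None,
               mode: Optional[str] = None, o2: Optional[float] = None) -> ResponseCurve:
    df, meta = _read_csv_with_meta(path)
    df = _apply_dialect(df, dialect)
    df, report = _validate_rows(df)
    if df.empty:
        raise EmptyInputError(f"{path}: no valid rows")
    curve = ResponseCurve(
        df,
        mode=mode or meta.get("mode", "ACI"),
        o2=o2 if o2 is not None else float(meta.get("O2", 21.0)),
    )
    curve.report = report
    return curve


def write_curve(curve: ResponseCurve, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# mode: {curve.mode}\n")
        fh.write(f"# O2: {curve.o2}\n")
        curve.data.to_csv(fh, index=False)


def write_report(report: dict, path) -> None:
    """Persist a row-validation / processing report as JSON."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
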