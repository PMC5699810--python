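"""Readers and writers for cases, labels and metric bundles.

Cases travel as CSV with one row per case and columns named after the
schema variables; ``unknown`` is spelled out literally.  Labels travel
either in the package's wide CSV dialect (one row per case, per-rater
column groups) or as a spreadsheet workbook in the same wide layout, the
format physicians filled in 100-case batches.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .panel import LabelMatrix
from .schema import PatientCase, VariableSpec, default_schema, validate_case


class ReadError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Cases
# ---------------------------------------------------------------------------

def write_cases_csv(cases: list[PatientCase], path: str | Path,
                    schema: list[VariableSpec] | None = None) -> None:
    schema = schema or default_schema()
    cols = [s.name for s in schema]
    rows = []
    for c in cases:
        row = {"case_id": c.case_id, "split": c.split or ""}
        for name in cols:
            row[name] = c.values.get(name, "")
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_cases_csv(path: str | Path, schema: list[VariableSpec] | None = None,
                   validate: bool = True) -> list[PatientCase]:
    schema = schema or default_schema()
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    by_name = {s.name: s for s in schema}
    cases = []
    for _, row in df.iterrows():
        values: dict[str, object] = {}
        for name, spec in by_name.items():
            raw = row.get(name, "")
            if spec.kind == "continuous" and raw.strip().lower() != "unknown":
                values[name] = float(raw)
            else:
                values[name] = raw
        case = PatientCase(case_id=row["case_id"], values=values,
                           split=row.get("split") or None)
        if validate:
            report = validate_case(case, schema)
            if not report.ok:
                raise ReadError(f"invalid case {case.case_id}: {report.violations}")
        cases.append(case)
    return cases


# ---------------------------------------------------------------------------
# Labels: wide dialect (CSV and spreadsheet workbook)
# ---------------------------------------------------------------------------

_LABEL_COLS = {
    "triage": "{r}_triage",
    "exacerbation": "{r}_exacerbation",
    "triage_confidence": "{r}_triage_confidence",
    "exacerbation_confidence": "{r}_exacerbation_confidence",
}


def write_labels_csv(labels: LabelMatrix, path: str | Path) -> None:
    """One row per case; four columns per rater."""
    wide = pd.DataFrame(index=pd.Index(labels.cases, name="case_id"))
    for col, pattern in _LABEL_COLS.items():
        piv = labels.pivot(col)
        for r in piv.columns:
            wide[pattern.format(r=r)] = piv[r]
    wide.reset_index().to_csv(path, index=False)


@dataclass
class LabelReadReport:
    labels: LabelMatrix | None
    errors: list[str]


_TRIAGE_RE = re.compile(r"(?i)triage")
_EXAC_RE = re.compile(r"(?i)exac")
_CONF_RE = re.compile(r"(?i)conf")
_CASE_RE = re.compile(r"(?i)case")


def _classify_header(header: str) -> tuple[str, str] | None:
    """Map a wide-format column header to (rater_id, label kind)."""
    if _TRIAGE_RE.search(header):
        kind = "triage_confidence" if _CONF_RE.search(header) else "triage"
        rater = _TRIAGE_RE.split(header)[0]
    elif _EXAC_RE.search(header):
        kind = "exacerbation_confidence" if _CONF_RE.search(header) else "exacerbation"
        rater = _EXAC_RE.split(header)[0]
    else:
        return None
    rater = rater.strip(" _-").strip()
    if not rater:
        return None
    return rater, kind


def _frame_to_labels(df: pd.DataFrame, fail_fast: bool) -> LabelReadReport:
    case_col = None
    for c in df.columns:
        if _CASE_RE.search(str(c)):
            case_col = c
            break
    if case_col is None:
        case_col = df.columns[0]
    errors: list[str] = []
    records: list[dict] = []
    per_case: dict[tuple[str, str], dict] = {}
    for col in df.columns:
        if col == case_col:
            continue
        parsed = _classify_header(str(col))
        if parsed is None:
            continue
        rater, kind = parsed
        for line, (cid, val) in enumerate(zip(df[case_col], df[col]), start=2):
            key = (rater, str(cid))
            entry = per_case.setdefault(
                key,
                dict(rater_id=rater, case_id=str(cid), triage=np.nan,
                     exacerbation=np.nan, triage_confidence=0.0,
                     exacerbation_confidence=0.0),
            )
            try:
                x = float(val)
            except (TypeError, ValueError):
                msg = f"line {line}: {col} = {val!r} not numeric"
                if fail_fast:
                    raise ReadError(msg)
                errors.append(msg)
                continue
            if kind == "triage" and x not in (1, 2, 3, 4):
                msg = f"line {line}: triage = {x} outside 1..4 ({col})"
                if fail_fast:
                    raise ReadError(msg)
                errors.append(msg)
                continue
            if kind == "exacerbation" and x not in (0, 1):
                msg = f"line {line}: exacerbation = {x} not 0/1 ({col})"
                if fail_fast:
                    raise ReadError(msg)
                errors.append(msg)
                continue
            if kind.endswith("confidence") and not (0 <= x <= 100):
                msg = f"line {line}: confidence = {x} outside [0, 100] ({col})"
                if fail_fast:
                    raise ReadError(msg)
                errors.append(msg)
                continue
            entry[kind] = x
    for entry in per_case.values():
        if np.isnan(entry["triage"]) or np.isnan(entry["exacerbation"]):
            errors.append(
                f"rater {entry['rater_id']} case {entry['case_id']}: incomplete labels dropped"
            )
            continue
        entry["triage"] = int(entry["triage"])
        entry["exacerbation"] = int(entry["exacerbation"])
        records.append(entry)
    if not records:
        return LabelReadReport(labels=None, errors=errors or ["no label columns found"])
    return LabelReadReport(labels=LabelMatrix.from_records(records), errors=errors)


def read_labels(path: str | Path, dialect: str = "csv", fail_fast: bool = False) -> LabelReadReport:
    """Read a label table in the ``csv`` or ``workbook`` (spreadsheet) dialect.

    Rows with out-of-range categories are rejected with line-number
    diagnostics collected in the report (or raised when ``fail_fast``).
    """
    if dialect == "csv":
        df = pd.read_csv(path)
    elif dialect == "workbook":
        df = pd.read_excel(path, engine="openpyxl")
    else:
        raise ReadError(f"unknown dialect {dialect!r}")
    return _frame_to_labels(df, fail_fast=fail_fast)
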