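"""CSV reading and writing for case records and score sheets.

Conventions: UTF-8, RFC-4180 quoting, "." decimal separator. Files written
by this module carry a metadata comment header (lines starting with ``#``)
recording the tool version, rubric version and seed; readers skip comment
lines. Output is assembled in memory and written atomically (temp file +
rename), so a failed run never leaves a partial file behind.
"""

from __future__ import annotations

import dataclasses
import io as _stdio
import logging
import os
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from . import __version__
from .errors import SchemaError
from .records import CaseRecord, ScoreSheet, case_field_names
from .rubric import Rubric, build_score_sheet

logger = logging.getLogger(__name__)

_FLOAT_FIELDS = {"age", "bmi", "hba1c", "expected_or_time"}
_INT_FIELDS = {"parity"}
_BOOL_FIELDS = {"immunocompromised"}
_OPTIONAL_CASE_FIELDS = {"hba1c", "acuity_tier"}

SHEET_ID_COLUMNS = ["case_id", "rater_id", "rater_role"]
SHEET_TAIL_COLUMNS = ["procedure_subtotal", "disease_subtotal",
                      "patient_subtotal", "total"]


def _parse_cell(field: str, raw: str, row: int):
    if raw is None or raw == "":
        return None
    try:
        if field in _FLOAT_FIELDS:
            return float(raw)
        if field in _INT_FIELDS:
            return int(float(raw))
        if field in _BOOL_FIELDS:
            low = raw.strip().lower()
            if low in ("true", "1", "yes"):
                return True
            if low in ("false", "0", "no"):
                return False
            raise ValueError(raw)
    except ValueError as exc:
        raise SchemaError(
            f"data row {row}, column {field!r}: could not parse {raw!r}"
        ) from exc
    return raw


def read_cases(path) -> list[CaseRecord]:
    """Read case records from CSV; errors carry row/column context."""
    df = pd.read_csv(path, comment="#", dtype=str, keep_default_na=False)
    required = [f for f in case_field_names() if f not in _OPTIONAL_CASE_FIELDS]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    known = set(case_field_names())
    unknown = [c for c in df.columns if c not in known]
    if unknown:
        logger.warning("%s: ignoring unknown column(s) %s", path, unknown)
    cases = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        values = {
            f: _parse_cell(f, getattr(row, f, ""), i)
            for f in case_field_names() if f in df.columns
        }
        try:
            cases.append(CaseRecord(**values).validate())
        except (ValueError, TypeError) as exc:
            raise SchemaError(f"data row {i}: {exc}") from exc
    return cases


def _metadata_header(rubric_version: str = "", seed: Optional[int] = None) -> str:
    lines = [f"# ments_version={__version__}"]
    if rubric_version:
        lines.append(f"# rubric_version={rubric_version}")
    if seed is not None:
        lines.append(f"# seed={seed}")
    return "\n".join(lines) + "\n"


def _atomic_write(path, text: str) -> None:
    path = Path(path)
    tmp = path.with_name(path.name + ".tmp")
    tmp.write_text(text, encoding="utf-8", newline="")
    os.replace(tmp, path)


def write_cases(cases: Sequence[CaseRecord], path, seed: Optional[int] = None) -> None:
    df = pd.DataFrame([dataclasses.asdict(c) for c in cases],
                      columns=case_field_names())
    _atomic_write(path, _metadata_header(seed=seed) + df.to_csv(index=False))


def write_scoresheets(sheets: Sequence[ScoreSheet], path,
                      rubric_version: str = "", seed: Optional[int] = None) -> None:
    """Write sheets as CSV: id columns, one column per factor (rubric order),
    subtotals, total. An empty sheet list yields a header-only file."""
    factor_order: list[str] = []
    for s in sheets:
        factor_order = list(s.factor_scores)
        break
    columns = SHEET_ID_COLUMNS + factor_order + SHEET_TAIL_COLUMNS
    rows = []
    for s in sheets:
        s.validate()
        row = {"case_id": s.case_id, "rater_id": s.rater_id,
               "rater_role": s.rater_role,
               **{f: s.factor_scores[f] for f in factor_order},
               "procedure_subtotal": s.procedure_subtotal,
               "disease_subtotal": s.disease_subtotal,
               "patient_subtotal": s.patient_subtotal, "total": s.total}
        rows.append(row)
    df = pd.DataFrame(rows, columns=columns)
    _atomic_write(path, _metadata_header(rubric_version, seed) + df.to_csv(index=False))


def read_scoresheets(path, rubric: Optional[Rubric] = None) -> list[ScoreSheet]:
    """Read score sheets; totals are re-verified against the factor scores.

    With a rubric, subtotals are recomputed from the rubric's component
    assignment; without one, the file's subtotal columns are trusted but the
    additivity and bound invariants are still enforced.
    """
    df = pd.read_csv(path, comment="#")
    missing = [c for c in SHEET_ID_COLUMNS + SHEET_TAIL_COLUMNS
               if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    factor_cols = [c for c in df.columns
                   if c not in SHEET_ID_COLUMNS + SHEET_TAIL_COLUMNS]
    if len(factor_cols) != 16:
        raise SchemaError(
            f"{path}: expected 16 factor columns, found {len(factor_cols)}"
        )
    sheets = []
    for i, row in df.iterrows():
        scores = {}
        for c in factor_cols:
            try:
                scores[c] = int(row[c])
            except (ValueError, TypeError) as exc:
                raise SchemaError(
                    f"data row {i + 1}, column {c!r}: could not parse {row[c]!r}"
                ) from exc
        if rubric is not None:
            sheet = build_score_sheet(rubric, str(row["case_id"]),
                                      str(row["rater_id"]),
                                      str(row["rater_role"]), scores)
        else:
            sheet = ScoreSheet(
                case_id=str(row["case_id"]), rater_id=str(row["rater_id"]),
                rater_role=str(row["rater_role"]), factor_scores=scores,
                procedure_subtotal=int(row["procedure_subtotal"]),
                disease_subtotal=int(row["disease_subtotal"]),
                patient_subtotal=int(row["patient_subtotal"]),
                total=int(row["total"]),
            ).validate()
        if sheet.total != int(row["total"]):
            raise SchemaError(
                f"data row {i + 1}: stored total {row['total']} does not match "
                f"recomputed total {sheet.total}"
            )
        sheets.append(sheet)
    return sheets
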