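"""Cohort-table validation: range, consistency and completeness checks.

Blocking errors (impossible values, internal contradictions) abort
analysis; warnings (missing optional fields) are reported but allow the
run to continue.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
import pandas as pd

from .errors import SchemaError

__all__ = ["Issue", "ValidationReport", "validate_cohort"]

REQUIRED_COLUMNS = ["id", "time", "event", "weight"]
PHQ_ITEM_COLUMNS = [f"phq{i}" for i in range(1, 10)]


@dataclass(frozen=True)
class Issue:
    """One validation finding, located by row label and column."""

    row: Optional[object]
    column: str
    message: str
    blocking: bool

    def __str__(self) -> str:
        where = f"row {self.row}, " if self.row is not None else ""
        level = "ERROR" if self.blocking else "WARNING"
        return f"{level}: {where}column {self.column}: {self.message}"


@dataclass
class ValidationReport:
    n_rows: int = 0
    errors: List[Issue] = field(default_factory=list)
    warnings: List[Issue] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors

    def raise_if_blocking(self) -> None:
        if self.errors:
            head = "; ".join(str(e) for e in self.errors[:5])
            raise SchemaError(
                f"cohort failed validation with {len(self.errors)} blocking "
                f"issue(s): {head}"
            )


def _flag_range(df, col, lo, hi, report, blocking=True, allow_nan=True):
    if col not in df.columns:
        return
    v = pd.to_numeric(df[col], errors="coerce")
    bad = (v < lo) | (v > hi)
    if not allow_nan:
        bad = bad | (v.isna() & df[col].notna())
    for row in df.index[bad.fillna(False)]:
        issue = Issue(row, col, f"value {df.at[row, col]!r} outside [{lo}, {hi}]",
                      blocking)
        (report.errors if blocking else report.warnings).append(issue)


def validate_cohort(df: pd.DataFrame) -> ValidationReport:
    """Check a cohort table against the analyzer's schema contract.

    Blocking: missing required columns; time ≤ 0; weight ≤ 0; event not in
    {0, 1}; PHQ items outside 0-3; utility outside [-1, 1]; phq_total
    disagreeing with the item sum on a complete row; neither PHQ items nor
    phq_total present; neither eq5d nor the Healthy Days columns present.
    Non-blocking: rows with incomplete PHQ-9 items (excluded downstream).
    """
    report = ValidationReport(n_rows=len(df))

    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            report.errors.append(
                Issue(None, col, "required column missing", True))
    if report.errors:
        return report

    t = pd.to_numeric(df["time"], errors="coerce")
    for row in df.index[(t <= 0) | t.isna()]:
        report.errors.append(
            Issue(row, "time", f"follow-up time {df.at[row, 'time']!r} must be > 0",
                  True))
    w = pd.to_numeric(df["weight"], errors="coerce")
    for row in df.index[(w <= 0) | w.isna()]:
        report.errors.append(
            Issue(row, "weight", f"weight {df.at[row, 'weight']!r} must be > 0",
                  True))
    e = pd.to_numeric(df["event"], errors="coerce")
    for row in df.index[~e.isin([0, 1])]:
        report.errors.append(
            Issue(row, "event", f"event {df.at[row, 'event']!r} must be 0 or 1",
                  True))

    for col in PHQ_ITEM_COLUMNS:
        _flag_range(df, col, 0, 3, report, blocking=True)
    _flag_range(df, "phq_total", 0, 27, report, blocking=True)
    _flag_range(df, "eq5d", -1.0, 1.0, report, blocking=True)
    _flag_range(df, "genhlth", 1, 5, report, blocking=True)
    for col in ("physdays", "mentdays", "actdays"):
        _flag_range(df, col, 0, 30, report, blocking=True)

    have_items = all(c in df.columns for c in PHQ_ITEM_COLUMNS)
    if not have_items and "phq_total" not in df.columns:
        report.errors.append(
            Issue(None, "phq_total", "need phq1..phq9 or phq_total", True))
    if have_items:
        items = df[PHQ_ITEM_COLUMNS].apply(pd.to_numeric, errors="coerce")
        in_range = items.notna() & (items >= 0) & (items <= 3)
        complete = in_range.all(axis=1)
        n_incomplete = int((~complete).sum())
        if n_incomplete:
            report.warnings.append(Issue(
                None, "phq1..phq9",
                f"{n_incomplete} row(s) with missing/invalid PHQ-9 items are "
                "excluded from severity analyses", False))
        if "phq_total" in df.columns:
            declared = pd.to_numeric(df["phq_total"], errors="coerce")
            both = complete & declared.notna()
            mismatch = both & (items.sum(axis=1) != declared)
            for row in df.index[mismatch]:
                report.errors.append(Issue(
                    row, "phq_total",
                    f"declared total {declared[row]:g} != item sum "
                    f"{items.loc[row].sum():g}", True))

    healthy_days = ["genhlth", "physdays", "mentdays", "actdays", "age"]
    if "eq5d" not in df.columns and not all(c in df.columns for c in healthy_days):
        report.errors.append(Issue(
            None, "eq5d",
            "need eq5d or the Healthy Days columns "
            f"{healthy_days} to obtain utilities", True))

    dup = df["id"].duplicated()
    for row in df.index[dup]:
        report.errors.append(
            Issue(row, "id", f"duplicate participant id {df.at[row, 'id']!r}", True))

    return report
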