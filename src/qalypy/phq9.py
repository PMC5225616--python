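"""PHQ-9 scoring and depressive-symptom severity classification.

The 9-item Patient Health Questionnaire asks about the frequency of nine
depression symptoms over the past two weeks; each item is coded 0 ("not at
all") to 3 ("nearly every day"), so the total ranges 0-27.  Totals are
binned into the conventional severity bands: none/minimal (0-4), mild
(5-9), moderate (10-14), moderately severe (15-19) and severe (20-27).
Because severe scores are rare in community samples of older adults, a
collapsed four-level classification merges moderately severe and severe
into one 15-27 band; both labellings are always carried.

Major depressive disorder (MDD) is operationalised as a total of 10 or
higher; mild depression as 5-9.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InputError

__all__ = [
    "SEVERITY_LABELS",
    "COLLAPSED_LABELS",
    "CATEGORY_RANGES",
    "COLLAPSED_RANGES",
    "SeverityCategory",
    "score_phq9",
    "categorize",
    "is_mdd",
    "phq_total_frame",
]

N_ITEMS = 9
MAX_ITEM = 3
MAX_TOTAL = N_ITEMS * MAX_ITEM  # 27

SEVERITY_LABELS = ("none_minimal", "mild", "moderate", "moderately_severe", "severe")
COLLAPSED_LABELS = ("none_minimal", "mild", "moderate", "modsev_severe")

#: inclusive total-score range per fine-grained severity band
CATEGORY_RANGES = {
    "none_minimal": (0, 4),
    "mild": (5, 9),
    "moderate": (10, 14),
    "moderately_severe": (15, 19),
    "severe": (20, 27),
}

#: inclusive range per collapsed band (moderately severe + severe merged)
COLLAPSED_RANGES = {
    "none_minimal": (0, 4),
    "mild": (5, 9),
    "moderate": (10, 14),
    "modsev_severe": (15, 27),
}

_COLLAPSE = {
    "none_minimal": "none_minimal",
    "mild": "mild",
    "moderate": "moderate",
    "moderately_severe": "modsev_severe",
    "severe": "modsev_severe",
}


@dataclass(frozen=True)
class SeverityCategory:
    """Severity assignment for one PHQ-9 total.

    Attributes
    ----------
    label : str
        Five-level band (``none_minimal`` .. ``severe``).
    collapsed_label : str
        Four-level band with moderately severe and severe merged
        (``modsev_severe``, covering totals 15-27).
    """

    label: str
    collapsed_label: str


def score_phq9(items: Sequence[int]) -> int:
    """Sum the nine item responses into the PHQ-9 total (0-27).

    Raises
    ------
    InputError
        If there are not exactly nine items, or an item falls outside
        {0, 1, 2, 3}; the message names the offending index.
    """
    items = list(items)
    if len(items) != N_ITEMS:
        raise InputError(f"PHQ-9 requires exactly {N_ITEMS} items, got {len(items)}")
    total = 0
    for i, v in enumerate(items):
        if not (isinstance(v, (int, np.integer)) and not isinstance(v, bool)):
            raise InputError(f"PHQ-9 item {i} is not an integer: {v!r}")
        if not 0 <= v <= MAX_ITEM:
            raise InputError(f"PHQ-9 item {i} out of range [0, {MAX_ITEM}]: {v}")
        total += int(v)
    return total


def _check_total(total: int) -> int:
    if not (isinstance(total, (int, np.integer)) and not isinstance(total, bool)):
        raise InputError(f"PHQ-9 total must be an integer, got {total!r}")
    if not 0 <= total <= MAX_TOTAL:
        raise InputError(f"PHQ-9 total out of range [0, {MAX_TOTAL}]: {total}")
    return int(total)


def categorize(total: int) -> SeverityCategory:
    """Map a PHQ-9 total to its severity band (five-level and collapsed)."""
    total = _check_total(total)
    for label, (lo, hi) in CATEGORY_RANGES.items():
        if lo <= total <= hi:
            return SeverityCategory(label=label, collapsed_label=_COLLAPSE[label])
    raise AssertionError("severity bands must partition 0-27")  # pragma: no cover


def is_mdd(total: int) -> bool:
    """Major depressive disorder indicator: PHQ-9 total of 10 or higher."""
    return _check_total(total) >= 10


def phq_total_frame(df: pd.DataFrame) -> pd.Series:
    """Resolve PHQ-9 totals for a cohort table.

    Uses ``phq1..phq9`` when present (validating each item), falling back to
    a precomputed ``phq_total`` column.  When both are present the recomputed
    sum must equal ``phq_total`` on every complete row.

    Returns a float Series: NaN where any item is missing (such records are
    excluded from severity analyses, with the count left to the caller's
    validation report).
    """
    item_cols = [f"phq{i}" for i in range(1, 10)]
    have_items = all(c in df.columns for c in item_cols)
    have_total = "phq_total" in df.columns
    if not have_items and not have_total:
        raise InputError("cohort has neither phq1..phq9 nor phq_total columns")

    if have_items:
        items = df[item_cols].astype(float)
        bad = ((items < 0) | (items > MAX_ITEM)) & items.notna()
        if bad.to_numpy().any():
            r, c = np.argwhere(bad.to_numpy())[0]
            raise InputError(
                f"PHQ-9 item out of range at row {df.index[r]}, column {item_cols[c]}"
            )
        total = items.sum(axis=1, skipna=False)
        if have_total:
            declared = df["phq_total"].astype(float)
            both = total.notna() & declared.notna()
            if not np.allclose(total[both], declared[both]):
                row = df.index[both & (total != declared)][0]
                raise InputError(
                    f"phq_total disagrees with the sum of phq1..phq9 at row {row}"
                )
        return total
    return df["phq_total"].astype(float)
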