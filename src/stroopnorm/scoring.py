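"""Raw score containers, derived difference indices, and cohort I/O.

A participant's performance on the four Stroop tasks is a :class:`ScorePanel`:
completion time in seconds (t1..t4) and error count out of 50 items (e1..e4).
Six difference indices quantify interference effects: reading interference
(T3-T1, E3-E1), naming interference (T4-T2, E4-E2) and resistance to
interference (T4-T3, E4-E3).  Negative differences are floored at zero — a
participant cannot exhibit "negative interference" for norming purposes.

Clinical records may carry partial panels (patients are often assessed only on
tasks 3 and 4); missing scores propagate as missing indices and are never
imputed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "ParticipantRecord",
    "ScorePanel",
    "DerivedIndices",
    "INDEX_NAMES",
    "SCORE_NAMES",
    "compute_indices",
    "read_cohort",
    "write_cohort",
    "cohort_to_frame",
]

#: canonical order of the twelve normed performance indices
SCORE_NAMES = (
    "T1", "T2", "T3", "T4", "E2", "E3", "E4",
    "T3-T1", "T4-T2", "T4-T3", "E4-E2", "E4-E3",
)

#: derived difference indices (column-name form)
INDEX_NAMES = ("t3_t1", "t4_t2", "t4_t3", "e3_e1", "e4_e2", "e4_e3")

#: analysis column -> canonical score name (E3-E1 is normed as the E3 family)
COLUMN_TO_SCORE = {
    "t1": "T1", "t2": "T2", "t3": "T3", "t4": "T4",
    "e2": "E2", "e3": "E3", "e4": "E4",
    "t3_t1": "T3-T1", "t4_t2": "T4-T2", "t4_t3": "T4-T3",
    "e4_e2": "E4-E2", "e4_e3": "E4-E3",
}
SCORE_TO_COLUMN = {v: k for k, v in COLUMN_TO_SCORE.items()}

_CSV_COLUMNS = ["id", "sex", "age", "education", "group",
                "t1", "e1", "t2", "e2", "t3", "e3", "t4", "e4"]

_GROUPS = ("healthy", "AD", "MCI")


@dataclass(frozen=True)
class ParticipantRecord:
    """Demographics and group label for one subject."""

    id: str
    sex: str
    age: float
    education: float
    group: str = "healthy"
    mmse: float | None = None

    def __post_init__(self):
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if self.group not in _GROUPS:
            raise ValueError(f"group must be one of {_GROUPS}, got {self.group!r}")
        if self.education < 0:
            raise ValueError("education must be >= 0")
        if self.group == "healthy" and not (20.0 <= self.age <= 90.0):
            raise ValueError("healthy normative records must have age in [20, 90]")


@dataclass(frozen=True)
class ScorePanel:
    """Raw task scores; ``None`` marks a missing measurement."""

    t1: float | None = None
    t2: float | None = None
    t3: float | None = None
    t4: float | None = None
    e1: float | None = None
    e2: float | None = None
    e3: float | None = None
    e4: float | None = None

    def __post_init__(self):
        for name in ("t1", "t2", "t3", "t4"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise ValueError(f"{name} must be strictly positive, got {v}")
        for name in ("e1", "e2", "e3", "e4"):
            v = getattr(self, name)
            if v is not None and not (0 <= v <= 50):
                raise ValueError(f"{name} must lie in [0, 50], got {v}")


@dataclass(frozen=True)
class DerivedIndices:
    """The six floored difference indices; ``None`` where an input was missing."""

    t3_t1: float | None = None
    t4_t2: float | None = None
    t4_t3: float | None = None
    e3_e1: float | None = None
    e4_e2: float | None = None
    e4_e3: float | None = None


def _floored_diff(a: float | None, b: float | None) -> float | None:
    if a is None or b is None:
        return None
    return max(0.0, float(a) - float(b))


def compute_indices(panel: ScorePanel) -> DerivedIndices:
    """Compute the six difference indices with the zero floor.

    Each index is ``max(0, minuend - subtrahend)``; a difference involving a
    missing score is itself missing.  Pure function of the panel.
    """
    return DerivedIndices(
        t3_t1=_floored_diff(panel.t3, panel.t1),
        t4_t2=_floored_diff(panel.t4, panel.t2),
        t4_t3=_floored_diff(panel.t4, panel.t3),
        e3_e1=_floored_diff(panel.e3, panel.e1),
        e4_e2=_floored_diff(panel.e4, panel.e2),
        e4_e3=_floored_diff(panel.e4, panel.e3),
    )


def cohort_to_frame(cohort: Iterable[tuple[ParticipantRecord, ScorePanel]],
                    indices: bool = True) -> pd.DataFrame:
    """Flatten (record, panel) pairs into an analysis DataFrame.

    With ``indices=True`` the six derived difference columns are appended.
    """
    rows = []
    for rec, panel in cohort:
        row = {
            "id": rec.id, "sex": rec.sex, "age": rec.age,
            "education": rec.education, "group": rec.group,
        }
        for f in fields(panel):
            v = getattr(panel, f.name)
            row[f.name] = np.nan if v is None else v
        if indices:
            der = compute_indices(panel)
            for f in fields(der):
                v = getattr(der, f.name)
                row[f.name] = np.nan if v is None else v
        rows.append(row)
    cols = _CSV_COLUMNS + (list(INDEX_NAMES) if indices else [])
    return pd.DataFrame(rows, columns=cols if rows else cols)


def write_cohort(cohort, path) -> None:
    """Write a cohort to CSV (missing values as empty fields)."""
    df = cohort_to_frame(cohort, indices=False)
    df.to_csv(path, index=False, columns=_CSV_COLUMNS)


def _parse_float(value, row_no: int, col: str, required: bool):
    if value is None or (isinstance(value, float) and math.isnan(value)) \
            or (isinstance(value, str) and value.strip() == ""):
        if required:
            raise ValueError(f"row {row_no}: missing mandatory field {col!r}")
        return None
    try:
        return float(value)
    except (TypeError, ValueError):
        raise ValueError(f"row {row_no}: cannot parse {col}={value!r}") from None


def read_cohort(path, on_error: str = "raise"):
    """Read a cohort CSV into (ParticipantRecord, ScorePanel) pairs.

    Rows with malformed or missing demographics are rejected with a
    diagnostic naming the row.  Missing raw scores are retained as explicit
    missing markers (patients are often assessed only on tasks 3 and 4).

    Parameters
    ----------
    on_error : {'raise', 'collect'}
        'raise' aborts on the first bad row; 'collect' returns
        ``(cohort, diagnostics)`` with bad rows skipped.
    """
    df = pd.read_csv(path, dtype={"id": str, "sex": str, "group": str},
                     comment="#", float_precision="round_trip")
    missing_cols = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"cohort file lacks columns {missing_cols}")

    cohort, diagnostics = [], []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header = line 1
        try:
            sex = str(row.sex).strip()
            group = str(row.group).strip() if isinstance(row.group, str) else "healthy"
            rec = ParticipantRecord(
                id=str(row.id), sex=sex,
                age=_parse_float(row.age, i, "age", required=True),
                education=_parse_float(row.education, i, "education", required=True),
                group=group,
            )
            panel = ScorePanel(**{
                c: _parse_float(getattr(row, c), i, c, required=False)
                for c in ("t1", "t2", "t3", "t4", "e1", "e2", "e3", "e4")
            })
        except ValueError as exc:
            if on_error == "raise":
                raise ValueError(f"row {i}: {exc}") from exc
            diagnostics.append(f"row {i}: {exc}")
            continue
        cohort.append((rec, panel))
    if on_error == "collect":
        return cohort, diagnostics
    return cohort
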