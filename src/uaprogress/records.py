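"""Data model for longitudinal urinalysis records and CSV input/output.

A treatment program is observed as a long-format table of test occasions:
one row per scheduled urinalysis, with a trinary outcome — ``negative``
(no drug metabolites detected), ``positive``, or ``missed`` (the patient
did not attend a scheduled test).  Weeks are patient-relative: week 1 is
the first week of that patient's program, so cohorts are aligned on
program week rather than calendar week.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "UrinalysisResult",
    "UrinalysisRecord",
    "PatientTrajectory",
    "RecordValidationError",
    "read_records",
    "write_records",
    "trajectories_to_frame",
    "frame_to_trajectories",
]

CSV_COLUMNS = ("patient_id", "week", "result")


class RecordValidationError(ValueError):
    """Raised when a record table violates the data-model invariants."""


class UrinalysisResult(str, enum.Enum):
    """Outcome of one scheduled urinalysis occasion."""

    NEGATIVE = "negative"
    POSITIVE = "positive"
    MISSED = "missed"

    @classmethod
    def from_token(cls, token: str) -> "UrinalysisResult":
        try:
            return cls(token)
        except ValueError:
            valid = ", ".join(m.value for m in cls)
            raise RecordValidationError(
                f"unknown result token {token!r}; expected one of: {valid}"
            ) from None


@dataclass(frozen=True, order=True)
class UrinalysisRecord:
    """One test occasion: patient, patient-relative program week, outcome."""

    patient_id: str
    week: int
    result: UrinalysisResult

    def __post_init__(self) -> None:
        if self.week < 1:
            raise RecordValidationError(
                f"week must be >= 1, got {self.week} for patient {self.patient_id!r}"
            )

    @property
    def attended(self) -> bool:
        """Whether the test was actually taken (result is not ``missed``)."""
        return self.result is not UrinalysisResult.MISSED


@dataclass
class PatientTrajectory:
    """A patient's full record sequence, sorted by program week.

    ``attributes`` holds optional caller-supplied baseline descriptors
    (booleans for prevalence rows, numbers for mean +/- sd rows) used by
    cohort summaries.
    """

    patient_id: str
    records: list[UrinalysisRecord] = field(default_factory=list)
    attributes: dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.records = sorted(self.records, key=lambda r: r.week)
        weeks = [r.week for r in self.records]
        if len(set(weeks)) != len(weeks):
            dupes = sorted({w for w in weeks if weeks.count(w) > 1})
            raise RecordValidationError(
                f"duplicate week(s) {dupes} for patient {self.patient_id!r}"
            )

    @property
    def weeks(self) -> list[int]:
        return [r.week for r in self.records]

    @property
    def attended_weeks(self) -> list[int]:
        return [r.week for r in self.records if r.attended]

    @property
    def n_attended(self) -> int:
        return sum(1 for r in self.records if r.attended)

    @property
    def last_attended_week(self) -> int | None:
        weeks = self.attended_weeks
        return weeks[-1] if weeks else None

    def __len__(self) -> int:
        return len(self.records)


def frame_to_trajectories(
    df: pd.DataFrame, program_length: int | None = None
) -> list[PatientTrajectory]:
    """Validate a long-format record table and group it by patient.

    Raises :class:`RecordValidationError` on unknown result tokens,
    duplicated ``(patient_id, week)`` pairs, or weeks outside
    ``[1, program_length]``.
    """
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise RecordValidationError(f"missing required column(s): {missing}")
    if df.empty:
        return []

    df = df.copy()
    df["patient_id"] = df["patient_id"].astype(str)
    try:
        df["week"] = df["week"].astype(int)
    except (ValueError, TypeError) as exc:
        raise RecordValidationError(f"non-integer week value: {exc}") from exc

    bad_week = df[(df["week"] < 1)]
    if program_length is not None:
        bad_week = df[(df["week"] < 1) | (df["week"] > program_length)]
    if not bad_week.empty:
        row = bad_week.iloc[0]
        raise RecordValidationError(
            f"week {row['week']} out of range [1, {program_length}] "
            f"for patient {row['patient_id']!r}"
        )

    dup = df.duplicated(subset=["patient_id", "week"])
    if dup.any():
        row = df[dup].iloc[0]
        raise RecordValidationError(
            f"duplicate (patient_id, week) pair: ({row['patient_id']!r}, {row['week']})"
        )

    trajectories: list[PatientTrajectory] = []
    for pid, group in df.groupby("patient_id", sort=True):
        recs = []
        for i, row in group.iterrows():
            result = UrinalysisResult.from_token(str(row["result"]))
            recs.append(UrinalysisRecord(str(pid), int(row["week"]), result))
        trajectories.append(PatientTrajectory(str(pid), recs))
    return trajectories


def trajectories_to_frame(trajectories: Iterable[PatientTrajectory]) -> pd.DataFrame:
    """Flatten trajectories back into a sorted long-format table."""
    rows = [
        (t.patient_id, r.week, r.result.value)
        for t in trajectories
        for r in t.records
    ]
    df = pd.DataFrame(rows, columns=list(CSV_COLUMNS))
    return df.sort_values(["patient_id", "week"], kind="stable").reset_index(drop=True)


def read_records(
    path: str | Path, program_length: int | None = None
) -> list[PatientTrajectory]:
    """Read a urinalysis record CSV into one trajectory per patient.

    The file must have a header row with columns ``patient_id``, ``week``,
    ``result``; result tokens are the lowercase strings ``negative`` /
    ``positive`` / ``missed``.  Row count is conserved: every input row
    becomes exactly one record.
    """
    df = pd.read_csv(path, dtype={"patient_id": str})
    return frame_to_trajectories(df, program_length=program_length)


def write_records(
    trajectories: Sequence[PatientTrajectory], path: str | Path
) -> None:
    """Write trajectories to CSV such that ``read_records`` round-trips exactly."""
    trajectories_to_frame(trajectories).to_csv(path, index=False)


def read_attributes(path: str | Path) -> dict[str, dict[str, object]]:
    """Read an optional patient-attribute CSV (``patient_id`` + columns).

    Values parse as booleans when the column is 0/1 or true/false, else
    numbers, else strings.  Returns ``patient_id -> {label: value}``.
    """
    df = pd.read_csv(path, dtype={"patient_id": str})
    if "patient_id" not in df.columns:
        raise RecordValidationError("attribute table must have a patient_id column")
    value_cols = [c for c in df.columns if c != "patient_id"]
    parsed: dict[str, list[object]] = {
        col: [_parse_token(v) for v in df[col]] for col in value_cols
    }
    # A column is boolean only if every value is boolean-like; this keeps a
    # numeric column with an incidental 0 or 1 (e.g. age) numeric.
    for col, values in parsed.items():
        if all(isinstance(v, bool) or v in (0.0, 1.0) for v in values):
            parsed[col] = [bool(v) for v in values]
    out: dict[str, dict[str, object]] = {}
    for i, pid in enumerate(df["patient_id"]):
        out[str(pid)] = {col: parsed[col][i] for col in value_cols}
    return out


def _parse_token(value: object) -> object:
    if isinstance(value, str):
        low = value.strip().lower()
        if low in {"true", "yes"}:
            return True
        if low in {"false", "no"}:
            return False
        try:
            return float(low)
        except ValueError:
            return value
    if isinstance(value, bool):
        return value
    if isinstance(value, (int, float)):
        return float(value)
    return value


def attach_attributes(
    trajectories: Sequence[PatientTrajectory],
    attributes: Mapping[str, Mapping[str, object]],
) -> None:
    """Attach attribute maps to trajectories in place, matching on patient_id."""
    for t in trajectories:
        if t.patient_id in attributes:
            t.attributes = dict(attributes[t.patient_id])
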