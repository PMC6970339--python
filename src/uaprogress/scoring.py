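"""Progress-bar scoring: per-test scores, patient curves, and group weekly series.

The scoring rule is the heart of the progress bar: each negative urinalysis
scores +1, each positive scores -1, and each missed test scores 0.  Summing
a patient's scores over their test occasions yields a cumulative "progress
bar" curve — steadily increasing under sustained abstinence, dipping on
relapse.

At the group level, ``score_i`` is the total score from all patients in
program week ``i`` and ``n_i`` is the number of patients who actually took
a urinalysis that week (missed tests count toward neither).  The
standardized weekly outcome is ``adjusted_score_i = score_i / n_i``, which
lies in [-1, 1] and is undefined on weeks with no tests taken.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

from .records import PatientTrajectory, UrinalysisResult

__all__ = [
    "ProgressBarSeries",
    "WeeklyGroupScore",
    "score_result",
    "patient_progress_series",
    "group_weekly_scores",
    "fill_missing_adjusted",
]

_SCORE = {
    UrinalysisResult.NEGATIVE: 1,
    UrinalysisResult.POSITIVE: -1,
    UrinalysisResult.MISSED: 0,
}


def score_result(result: UrinalysisResult) -> int:
    """Score one urinalysis outcome: negative -> +1, positive -> -1, missed -> 0."""
    return _SCORE[result]


@dataclass(frozen=True)
class ProgressBarSeries:
    """A patient's cumulative score curve over their test occasions.

    ``cumulative_scores[k]`` is the running sum of per-test scores through
    the k-th occasion, so consecutive values differ by -1, 0, or +1.
    """

    patient_id: str
    weeks: tuple[int, ...]
    cumulative_scores: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.weeks) != len(self.cumulative_scores):
            raise ValueError("weeks and cumulative_scores must have equal length")


@dataclass(frozen=True)
class WeeklyGroupScore:
    """Group-level score for one program week.

    ``score`` is the sum of all per-test scores in the week; ``n`` counts
    tests actually taken; ``adjusted_score`` is ``score / n`` or ``None``
    when nobody tested.
    """

    week: int
    score: int
    n: int
    adjusted_score: float | None

    def __post_init__(self) -> None:
        if abs(self.score) > self.n:
            raise ValueError(f"|score| = {abs(self.score)} exceeds n = {self.n}")
        if (self.adjusted_score is None) != (self.n == 0):
            raise ValueError("adjusted_score must be missing exactly when n == 0")


def patient_progress_series(trajectory: PatientTrajectory) -> ProgressBarSeries:
    """Compute a patient's cumulative progress-bar curve.

    An empty trajectory yields an empty series.
    """
    weeks: list[int] = []
    cumulative: list[int] = []
    total = 0
    for record in trajectory.records:
        total += score_result(record.result)
        weeks.append(record.week)
        cumulative.append(total)
    return ProgressBarSeries(trajectory.patient_id, tuple(weeks), tuple(cumulative))


def group_weekly_scores(
    trajectories: Sequence[PatientTrajectory], program_length: int
) -> list[WeeklyGroupScore]:
    """Aggregate per-test scores into one WeeklyGroupScore per week 1..program_length.

    Missed tests contribute neither to the numerator (their score is 0) nor
    to the denominator (the test was not taken), so a week of pure misses
    has ``n = 0`` and a missing adjusted score.
    """
    if program_length < 1:
        raise ValueError("program_length must be >= 1")
    score = [0] * (program_length + 1)
    n = [0] * (program_length + 1)
    for t in trajectories:
        for r in t.records:
            if r.week > program_length:
                raise ValueError(
                    f"record week {r.week} exceeds program_length {program_length}"
                )
            score[r.week] += score_result(r.result)
            if r.attended:
                n[r.week] += 1
    return [
        WeeklyGroupScore(
            week=i,
            score=score[i],
            n=n[i],
            adjusted_score=(score[i] / n[i]) if n[i] > 0 else None,
        )
        for i in range(1, program_length + 1)
    ]


FillPolicy = Literal["zero", "interpolate"]


def fill_missing_adjusted(
    series: Sequence[WeeklyGroupScore], policy: FillPolicy = "zero"
) -> list[float]:
    """Return one adjusted score per week, filling no-test weeks.

    ``zero`` fills missing weeks with 0.0 (no fabricated signal);
    ``interpolate`` fills linearly between the nearest observed neighbours
    and extends flat past the edges.  Interpolation requires at least one
    observed week.
    """
    values = [w.adjusted_score for w in series]
    if policy == "zero":
        return [v if v is not None else 0.0 for v in values]
    if policy != "interpolate":
        raise ValueError(f"unknown fill policy {policy!r}")

    present = [(i, v) for i, v in enumerate(values) if v is not None]
    if not present:
        raise ValueError("cannot interpolate: no weeks with an adjusted score")
    out = list(values)
    idx = [i for i, _ in present]
    for i in range(len(out)):
        if out[i] is not None:
            continue
        # nearest observed neighbours on each side; flat extension past edges
        left = max((j for j in idx if j < i), default=None)
        right = min((j for j in idx if j > i), default=None)
        if left is None:
            out[i] = values[right]  # type: ignore[index]
        elif right is None:
            out[i] = values[left]
        else:
            frac = (i - left) / (right - left)
            out[i] = values[left] + frac * (values[right] - values[left])  # type: ignore[operator]
    assert all(v is not None and math.isfinite(v) for v in out)  # type: ignore[arg-type]
    return out  # type: ignore[return-value]
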