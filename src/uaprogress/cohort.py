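"""Cohort eligibility filters and descriptive baseline summaries.

Mirrors the study-flow stages of a mandatory-treatment cohort: an
engagement filter (at least four attended outpatient visits), a recency
filter (last attended visit within 26 weeks of the study end, since longer
absences typically reflect judicial re-entry), and a completer filter
(sustained attendance across both program halves).  An "outpatient visit"
is operationalized as an attended test occasion (result != missed),
because visits and urinalyses are coupled in this protocol.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from statistics import mean, stdev
from typing import Sequence

from .records import PatientTrajectory

__all__ = [
    "FilterReport",
    "CohortSummaryRow",
    "filter_engagement",
    "filter_recency",
    "filter_completers",
    "summarize_cohort",
    "round_percent",
]

DEFAULT_MIN_VISITS = 4
DEFAULT_MAX_GAP = 26


@dataclass(frozen=True)
class FilterReport:
    """Accounting for one eligibility filter: input = excluded + retained."""

    rule: str
    n_input: int
    n_excluded: int
    n_retained: int

    def __post_init__(self) -> None:
        if self.n_input != self.n_excluded + self.n_retained:
            raise ValueError("filter must conserve patients")


@dataclass(frozen=True)
class CohortSummaryRow:
    """One descriptive-table row.

    Boolean attributes populate ``count``/``percent`` (of ``denominator``);
    continuous attributes populate ``mean``/``sd``.
    """

    label: str
    count: int | None = None
    percent: float | None = None
    mean: float | None = None
    sd: float | None = None


def round_percent(count: int, denominator: int) -> float:
    """One-decimal percentage with round-half-away-from-zero."""
    pct = Decimal(100 * count) / Decimal(denominator)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def _split(
    trajectories: Sequence[PatientTrajectory], keep, rule: str
) -> tuple[list[PatientTrajectory], FilterReport]:
    retained = [t for t in trajectories if keep(t)]
    report = FilterReport(
        rule=rule,
        n_input=len(trajectories),
        n_excluded=len(trajectories) - len(retained),
        n_retained=len(retained),
    )
    return retained, report


def filter_engagement(
    trajectories: Sequence[PatientTrajectory], min_visits: int = DEFAULT_MIN_VISITS
) -> tuple[list[PatientTrajectory], FilterReport]:
    """Retain patients with at least ``min_visits`` attended test occasions."""
    if min_visits < 1:
        raise ValueError("min_visits must be >= 1")
    return _split(
        trajectories,
        lambda t: t.n_attended >= min_visits,
        rule=f"engagement(min_visits={min_visits})",
    )


def filter_recency(
    trajectories: Sequence[PatientTrajectory],
    study_end_week: int,
    max_gap: int = DEFAULT_MAX_GAP,
) -> tuple[list[PatientTrajectory], FilterReport]:
    """Retain patients whose last attended week is within ``max_gap`` of study end.

    A patient with no attended visits has no "most recent visit" and is
    excluded by convention.
    """
    if study_end_week < 1:
        raise ValueError("study_end_week must be >= 1")

    def keep(t: PatientTrajectory) -> bool:
        last = t.last_attended_week
        return last is not None and last >= study_end_week - max_gap

    return _split(
        trajectories, keep, rule=f"recency(study_end_week={study_end_week}, max_gap={max_gap})"
    )


def filter_completers(
    trajectories: Sequence[PatientTrajectory],
    program_length: int,
    split_week: int = 27,
    max_gap: int = DEFAULT_MAX_GAP,
) -> tuple[list[PatientTrajectory], FilterReport]:
    """Retain program completers.

    Completion is operationalized as at least one attended occasion in each
    program half (weeks 1..split_week-1 and split_week..program_length) and
    a last attended occasion within ``max_gap`` weeks of the program end.
    """
    if program_length < 1:
        raise ValueError("program_length must be >= 1")
    if not 1 < split_week <= program_length:
        raise ValueError("split_week must be in (1, program_length]")

    def keep(t: PatientTrajectory) -> bool:
        attended = t.attended_weeks
        if not attended:
            return False
        first_half = any(w < split_week for w in attended)
        second_half = any(split_week <= w <= program_length for w in attended)
        recent = attended[-1] >= program_length - max_gap
        return first_half and second_half and recent

    return _split(
        trajectories,
        keep,
        rule=f"completion(program_length={program_length}, split_week={split_week})",
    )


def summarize_cohort(
    trajectories: Sequence[PatientTrajectory], denominator: int | None = None
) -> list[CohortSummaryRow]:
    """Build a descriptive baseline table from caller-supplied attributes.

    Boolean attributes become ``count (percent)`` rows over ``denominator``
    (default: the cohort size); numeric attributes become ``mean +/- sd``
    rows over the patients providing a value.
    """
    if denominator is None:
        denominator = len(trajectories)
    if denominator < 1:
        raise ValueError("denominator must be >= 1")

    labels: list[str] = []
    for t in trajectories:
        for key in t.attributes:
            if key not in labels:
                labels.append(key)

    rows: list[CohortSummaryRow] = []
    for label in labels:
        values = [t.attributes[label] for t in trajectories if label in t.attributes]
        bools = [v for v in values if isinstance(v, bool)]
        if bools and len(bools) == len(values):
            count = sum(bools)
            rows.append(
                CohortSummaryRow(
                    label=label, count=count, percent=round_percent(count, denominator)
                )
            )
        else:
            numbers = [float(v) for v in values if isinstance(v, (int, float))]
            if not numbers:
                continue
            rows.append(
                CohortSummaryRow(
                    label=label,
                    mean=mean(numbers),
                    sd=stdev(numbers) if len(numbers) > 1 else 0.0,
                )
            )
    return rows
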