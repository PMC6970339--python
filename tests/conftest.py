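import numpy as np
import pytest

from uaprogress.records import PatientTrajectory, UrinalysisRecord, UrinalysisResult

NEG = UrinalysisResult.NEGATIVE
POS = UrinalysisResult.POSITIVE
MISS = UrinalysisResult.MISSED


def make_trajectory(patient_id, week_results):
    """Build a trajectory from [(week, result), ...] pairs."""
    return PatientTrajectory(
        patient_id,
        [UrinalysisRecord(patient_id, w, r) for w, r in week_results],
    )


@pytest.fixture
def small_cohort():
    """Three patients with mixed outcomes over a 10-week window."""
    return [
        make_trajectory("a", [(2, NEG), (4, NEG), (6, POS), (8, NEG)]),
        make_trajectory("b", [(2, POS), (4, MISS), (6, NEG), (8, NEG)]),
        make_trajectory("c", [(2, NEG), (4, NEG), (6, NEG), (8, MISS)]),
    ]


def random_cohort(rng: np.random.Generator, max_records: int = 200,
                  program_length: int = 52):
    """Random valid dataset: unique (patient, week) pairs, random outcomes."""
    n_patients = int(rng.integers(1, 12))
    results = list(UrinalysisResult)
    cohort = []
    total = 0
    for i in range(n_patients):
        budget = max_records - total
        if budget <= 0:
            break
        n = int(rng.integers(0, min(program_length, budget) + 1))
        weeks = rng.choice(np.arange(1, program_length + 1), size=n, replace=False)
        recs = [
            UrinalysisRecord(f"p{i}", int(w), results[rng.integers(0, 3)])
            for w in weeks
        ]
        total += n
        cohort.append(PatientTrajectory(f"p{i}", recs))
    return cohort
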