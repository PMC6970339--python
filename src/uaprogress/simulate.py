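"""Synthetic-cohort simulator for the two-phase urinalysis protocol.

The treatment protocol is a small state machine per patient:

* **High-demand phase** — urinalysis every 2 weeks.  Accumulating
  ``stabilization_threshold`` (default 4) negative samples since the last
  positive result triggers "stabilization" and the switch to the
  low-demand phase.
* **Low-demand phase** — urinalysis every 4 weeks ("monthly" on the
  integer week grid).  Any positive result sends the patient back to the
  biweekly high-demand schedule and resets the stabilization counter.
* **Missed appointments** delay the next test by exactly 1 week instead
  of a full interval.  This is the minimal mechanism that reproduces the
  characteristic parity drift of biweekly schedules: perfectly attending
  patients test only on even program weeks, while accumulated misses
  spread tests onto odd weeks as the program progresses.
* **Dropout** is a per-occasion Bernoulli event with no re-entry.

Default outcome probabilities are calibrated so that the expected
stabilization time is about 6 months: with per-test relapse probability
0.3 and miss probability 0.2, a patient needs on average ~10.5 attended
tests (the expected waiting time for 4 successes at success rate 0.7 with
reset on failure), or ~13 scheduled occasions, putting the mean phase
transition near week 26 of a 52-week program.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace

import numpy as np

from .records import PatientTrajectory, UrinalysisRecord, UrinalysisResult

__all__ = [
    "Phase",
    "PhaseState",
    "ProtocolConfig",
    "SimulationConfig",
    "step_patient",
    "simulate_patient",
    "simulate_cohort",
]


class Phase(str, enum.Enum):
    HIGH_DEMAND = "high_demand"
    LOW_DEMAND = "low_demand"


@dataclass(frozen=True)
class ProtocolConfig:
    """Protocol constants: testing intervals, stabilization rule, program span."""

    program_length: int = 52
    high_demand_interval: int = 2
    low_demand_interval: int = 4
    stabilization_threshold: int = 4
    split_week: int = 27
    missed_delay: int = 1

    def __post_init__(self) -> None:
        for name in (
            "program_length",
            "high_demand_interval",
            "low_demand_interval",
            "stabilization_threshold",
            "split_week",
            "missed_delay",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.split_week > self.program_length:
            raise ValueError("split_week must be <= program_length")

    def interval(self, phase: Phase) -> int:
        return (
            self.high_demand_interval
            if phase is Phase.HIGH_DEMAND
            else self.low_demand_interval
        )


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters for a synthetic cohort."""

    n_patients: int = 312
    p_positive_high: float = 0.3
    p_positive_low: float = 0.15
    p_missed: float = 0.2
    p_dropout_per_occasion: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        for name in ("p_positive_high", "p_positive_low", "p_missed", "p_dropout_per_occasion"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be a probability in [0, 1], got {p}")

    def p_positive(self, phase: Phase) -> float:
        return self.p_positive_high if phase is Phase.HIGH_DEMAND else self.p_positive_low


@dataclass(frozen=True)
class PhaseState:
    """A patient's position in the protocol state machine.

    ``next_test_week`` is the week of the upcoming scheduled test;
    ``negatives_toward_stabilization`` counts negative samples since the
    last positive (only meaningful in the high-demand phase).
    """

    phase: Phase = Phase.HIGH_DEMAND
    negatives_toward_stabilization: int = 0
    next_test_week: int = 2

    def __post_init__(self) -> None:
        if self.negatives_toward_stabilization < 0:
            raise ValueError("stabilization counter must be >= 0")


def step_patient(
    state: PhaseState, outcome: UrinalysisResult, config: ProtocolConfig
) -> PhaseState:
    """Advance the protocol state machine by one test occasion.

    The occasion happens at ``state.next_test_week``; the returned state
    carries the week of the following test.  Rules:

    * negative in high-demand increments the stabilization counter; on
      reaching the threshold the patient transitions to low-demand and the
      counter resets;
    * a positive in either phase returns the patient to high-demand with
      the counter reset (full restart of the 4-negative requirement);
    * a missed test leaves phase and counter untouched but delays the next
      test by ``missed_delay`` weeks (schedule drift);
    * otherwise the next test is one phase interval after this one.
    """
    week = state.next_test_week
    if outcome is UrinalysisResult.MISSED:
        return replace(state, next_test_week=week + config.missed_delay)

    if outcome is UrinalysisResult.POSITIVE:
        phase = Phase.HIGH_DEMAND
        counter = 0
    else:  # negative
        phase = state.phase
        counter = state.negatives_toward_stabilization
        if phase is Phase.HIGH_DEMAND:
            counter += 1
            if counter >= config.stabilization_threshold:
                phase = Phase.LOW_DEMAND
                counter = 0

    return PhaseState(
        phase=phase,
        negatives_toward_stabilization=counter,
        next_test_week=week + config.interval(phase),
    )


def _draw_outcome(
    rng: np.random.Generator, phase: Phase, sim: SimulationConfig
) -> UrinalysisResult:
    if rng.random() < sim.p_missed:
        return UrinalysisResult.MISSED
    if rng.random() < sim.p_positive(phase):
        return UrinalysisResult.POSITIVE
    return UrinalysisResult.NEGATIVE


def simulate_patient(
    protocol: ProtocolConfig,
    sim: SimulationConfig,
    rng: np.random.Generator,
    patient_id: str = "p0",
) -> PatientTrajectory:
    """Simulate one patient through the protocol until dropout or program end."""
    state = PhaseState(next_test_week=protocol.high_demand_interval)
    records: list[UrinalysisRecord] = []
    while state.next_test_week <= protocol.program_length:
        outcome = _draw_outcome(rng, state.phase, sim)
        records.append(UrinalysisRecord(patient_id, state.next_test_week, outcome))
        state = step_patient(state, outcome, protocol)
        if rng.random() < sim.p_dropout_per_occasion:
            break
    return PatientTrajectory(patient_id, records)


def simulate_cohort(
    protocol: ProtocolConfig, sim: SimulationConfig
) -> list[PatientTrajectory]:
    """Simulate ``sim.n_patients`` independent trajectories.

    Each patient gets an independent substream spawned from one master
    seed sequence, so cohorts are reproducible under a fixed seed and a
    patient's trajectory does not depend on how many others are simulated
    before it.
    """
    master = np.random.SeedSequence(sim.seed)
    children = master.spawn(sim.n_patients)
    width = len(str(sim.n_patients - 1))
    return [
        simulate_patient(
            protocol, sim, np.random.default_rng(child), patient_id=f"p{str(i).zfill(width)}"
        )
        for i, child in enumerate(children)
    ]


def stabilization_week(
    trajectory: PatientTrajectory, protocol: ProtocolConfig
) -> int | None:
    """Week of first transition to the low-demand phase, or None if never reached.

    Replays the state machine over the recorded outcomes.
    """
    state = PhaseState(next_test_week=protocol.high_demand_interval)
    for record in trajectory.records:
        new = step_patient(replace(state, next_test_week=record.week), record.result, protocol)
        if state.phase is Phase.HIGH_DEMAND and new.phase is Phase.LOW_DEMAND:
            return record.week
        state = new
    return None
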