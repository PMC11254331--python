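"""Cohort selection and the explorer summary operations.

A cohort is defined the way the interactive explorers do it: pick a
treatment arm, a symptom term, the severity level at an initial
timepoint, and a final timepoint. Everyone in that arm whose state for
the term at the initial timepoint equals the chosen level is in; their
trajectories are clipped to the [start, end] stage window.

Three summaries are computed on the selected trajectories:

* :func:`final_state_summary` — the plain-language statement tallying
  where the cohort ended up, e.g. "Of the initial 18 patients, 12 (67%)
  were Off Treatment, ...". Percentages are rounded to whole numbers,
  half away from zero, against the *initial* cohort size, and are not
  force-balanced to 100 (a 67 + 28 + 6 = 101 outcome is faithful).
* :func:`grade_duration` — for each severity state, how its occurrences
  distribute over the window's cycles. The unit is the patient-cycle
  cell, not the patient: a patient at grade 3 in two cycles contributes
  two grade-3 cases.
* the Toxicity Index distribution (see :mod:`toxflow.toxicity_index`).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Mapping

from .data_model import ObservationTable, TrajectoryMatrix, pivot_trajectories
from .errors import UnknownLabelError

__all__ = [
    "CohortQuery",
    "select_cohort",
    "FinalStateSummary",
    "final_state_summary",
    "grade_duration",
    "round_percent",
]


def round_percent(count: int, total: int) -> int:
    """Whole-number percentage, rounded half away from zero."""
    if total <= 0:
        raise ValueError("total must be positive")
    return int(math.floor(100.0 * count / total + 0.5))


@dataclass(frozen=True)
class CohortQuery:
    """Arm + term + initial severity level + [start, end] stage window."""

    arm: str
    term: str
    initial_level: str
    start_stage: str
    end_stage: str


def select_cohort(table: ObservationTable, query: CohortQuery) -> TrajectoryMatrix:
    """Select the patients matching a cohort query.

    Returns exactly the patients in ``query.arm`` whose (filled) state for
    ``query.term`` at ``query.start_stage`` equals ``query.initial_level``,
    with stages clipped to the window. Zero matches give an empty matrix,
    which is a valid result, not an error; unknown labels raise.
    """
    scale = table.scale
    if query.initial_level not in scale.all_states:
        raise UnknownLabelError(f"initial level {query.initial_level!r} not in scale")
    for st in (query.start_stage, query.end_stage):
        if st not in table.stage_order:
            raise UnknownLabelError(f"stage {st!r} not in stage order")
    i0 = table.stage_order.index(query.start_stage)
    i1 = table.stage_order.index(query.end_stage)
    if i0 >= i1:
        raise ValueError("the cohort window must span at least two stages")
    stages = table.stage_order[i0 : i1 + 1]

    full = pivot_trajectories(table, query.term, query.arm, stages)
    keep = [
        k for k, row in enumerate(full.states) if row[0] == query.initial_level
    ]
    return TrajectoryMatrix(
        scale=scale,
        patient_ids=tuple(full.patient_ids[k] for k in keep),
        stages=stages,
        states=tuple(full.states[k] for k in keep),
    )


@dataclass(frozen=True)
class FinalStateSummary:
    """Tally of the cohort's states at the final stage, plus the statement."""

    cohort_size: int
    final_stage: str
    counts: Mapping[str, int]
    percents: Mapping[str, int]
    statement: str

    def to_dict(self) -> dict:
        return {
            "cohort_size": self.cohort_size,
            "final_stage": self.final_stage,
            "counts": dict(self.counts),
            "percents": dict(self.percents),
            "statement": self.statement,
        }

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("sort_keys", True)
        kwargs.setdefault("indent", 2)
        return json.dumps(self.to_dict(), **kwargs)


def final_state_summary(trajectories: TrajectoryMatrix) -> FinalStateSummary:
    """Tally last-stage states and render the plain-language statement.

    Categories appear in descending count order, ties broken most severe
    first (missing level last). Percent denominators are the initial
    cohort size, so patients off treatment stay in the denominator.
    """
    n = trajectories.n_patients
    if n < 1:
        raise ValueError("cannot summarise an empty cohort")
    scale = trajectories.scale
    final_stage = trajectories.stages[-1]
    tally: dict[str, int] = {}
    for row in trajectories.states:
        tally[row[-1]] = tally.get(row[-1], 0) + 1
    ordered = sorted(tally, key=lambda s: (-tally[s], scale.display_rank(s)))
    counts = {s: tally[s] for s in ordered}
    percents = {s: round_percent(tally[s], n) for s in ordered}
    parts = [f"{counts[s]} ({percents[s]}%) were {s}" for s in ordered]
    if len(parts) > 1:
        body = ", ".join(parts[:-1]) + ", and " + parts[-1]
    else:
        body = parts[0]
    statement = f"Of the initial {n} patients, {body} by {final_stage}."
    return FinalStateSummary(
        cohort_size=n,
        final_stage=final_stage,
        counts=counts,
        percents=percents,
        statement=statement,
    )


def grade_duration(
    trajectories: TrajectoryMatrix, include_missing: bool = False
) -> dict[str, dict[str, int]]:
    """For each state, the percentage split of its occurrences over stages.

    The denominator for state g is the total number of patient-stage
    cells equal to g in the window, so each state's row sums to 100 up to
    per-stage rounding. The missing/off-treatment level is excluded
    unless ``include_missing`` is set. Only states that occur are
    reported.
    """
    if trajectories.n_patients < 1:
        raise ValueError("cannot summarise an empty cohort")
    scale = trajectories.scale
    counts: dict[str, dict[str, int]] = {}
    for row in trajectories.states:
        for st, s in zip(trajectories.stages, row):
            if s == scale.missing_level and not include_missing:
                continue
            counts.setdefault(s, {}).setdefault(st, 0)
            counts[s][st] += 1
    result: dict[str, dict[str, int]] = {}
    for s in scale.all_states:
        if s not in counts:
            continue
        total = sum(counts[s].values())
        result[s] = {
            st: round_percent(counts[s].get(st, 0), total)
            for st in trajectories.stages
            if counts[s].get(st, 0) > 0
        }
    return result
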