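"""Canonical data structures for longitudinal tolerability observations.

A trial extract is modelled as a long-format set of observations — one
severity level per (patient, symptom term, timepoint) — governed by a
single ordered :class:`SeverityScale` (for example CTCAE grades 0..5, or
the BCPT bother levels "Not at all" … "Extremely"). Absent assessments
are represented by the scale's designated missing level ("Off Treatment"
for clinician-graded adverse events, "No Response" for patient-reported
outcomes), which is a display category of its own, not a hidden NA.

The pivoted, rectangular view of one term within one arm is a
:class:`TrajectoryMatrix`: one state per patient per stage, with absent
cells filled by the missing level. Every downstream computation (flow
graphs, Toxicity Index, cohort summaries) consumes trajectories.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import pandas as pd

from .errors import NoMatchingRecordsError, ValidationError

__all__ = [
    "SeverityScale",
    "Observation",
    "ObservationTable",
    "TrajectoryMatrix",
    "ValidationFinding",
    "validate_table",
    "assert_valid",
    "pivot_trajectories",
]


@dataclass(frozen=True)
class SeverityScale:
    """An ordered severity scale plus a terminal missing/off-study category.

    Parameters
    ----------
    name:
        Short label, e.g. ``"CTCAE"`` or ``"BCPT"``.
    levels:
        Level labels ordered least to most severe.
    missing_level:
        Label used for absent or off-treatment observations. It is not a
        member of ``levels``; it is appended as an extra display category.
    grade_values:
        Optional map from level label to a numeric grade. Required for
        Toxicity Index computation. Values must be finite, non-negative
        and non-decreasing along the level order.
    """

    name: str
    levels: tuple[str, ...]
    missing_level: str
    grade_values: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "levels", tuple(self.levels))
        if not self.levels:
            raise ValueError("a severity scale needs at least one level")
        if len(set(self.levels)) != len(self.levels):
            raise ValueError(f"duplicate level labels in scale {self.name!r}")
        if self.missing_level in self.levels:
            raise ValueError(
                f"missing_level {self.missing_level!r} must not be an ordinary level"
            )
        if self.grade_values is not None:
            gv = {str(k): float(v) for k, v in dict(self.grade_values).items()}
            object.__setattr__(self, "grade_values", gv)
            absent = [lv for lv in self.levels if lv not in gv]
            if absent:
                raise ValueError(f"grade_values missing for levels {absent}")
            vals = [gv[lv] for lv in self.levels]
            if any(not math.isfinite(v) or v < 0 for v in vals):
                raise ValueError("grade values must be finite and >= 0")
            if any(b < a for a, b in zip(vals, vals[1:])):
                raise ValueError("grade values must be non-decreasing with severity")

    @property
    def all_states(self) -> tuple[str, ...]:
        """Levels plus the missing level (the full display vocabulary)."""
        return self.levels + (self.missing_level,)

    @property
    def display_order(self) -> tuple[str, ...]:
        """Top-to-bottom node order: most severe first, missing level last."""
        return tuple(reversed(self.levels)) + (self.missing_level,)

    def display_rank(self, state: str) -> int:
        return self.display_order.index(state)

    def grade_of(self, level: str) -> float:
        if self.grade_values is None:
            raise ValueError(f"scale {self.name!r} has no grade_values")
        return self.grade_values[level]

    def severity_rank(self, state: str) -> int:
        """Ordinal position of a state; the missing level ranks below level 0."""
        if state == self.missing_level:
            return -1
        return self.levels.index(state)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "levels": list(self.levels),
            "missing_level": self.missing_level,
            "grade_values": dict(self.grade_values) if self.grade_values else None,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "SeverityScale":
        return cls(
            name=d["name"],
            levels=tuple(d["levels"]),
            missing_level=d["missing_level"],
            grade_values=d.get("grade_values"),
        )


class Observation(NamedTuple):
    """One severity assessment of one patient at one timepoint."""

    patient_id: str
    arm: str
    term: str
    timepoint: str
    level: str


@dataclass(frozen=True)
class ObservationTable:
    """Long-format store of observations under a single scale.

    Observations are canonicalised (sorted) at construction, so two tables
    built from the same records in any order compare equal.
    """

    scale: SeverityScale
    stage_order: tuple[str, ...]
    observations: tuple[Observation, ...] = field(default=())

    def __post_init__(self) -> None:
        object.__setattr__(self, "stage_order", tuple(self.stage_order))
        if len(set(self.stage_order)) != len(self.stage_order):
            raise ValueError("stage_order entries must be unique")
        stage_idx = {s: i for i, s in enumerate(self.stage_order)}
        n_stages = len(self.stage_order)

        def key(o: Observation):
            return (
                o.patient_id,
                o.arm,
                o.term,
                stage_idx.get(o.timepoint, n_stages),
                o.timepoint,
                o.level,
            )

        obs = tuple(sorted((Observation(*o) for o in self.observations), key=key))
        object.__setattr__(self, "observations", obs)

    # -- views -----------------------------------------------------------
    def __len__(self) -> int:
        return len(self.observations)

    def patients(self) -> tuple[str, ...]:
        return tuple(sorted({o.patient_id for o in self.observations}))

    def arms(self) -> tuple[str, ...]:
        return tuple(sorted({o.arm for o in self.observations}))

    def terms(self) -> tuple[str, ...]:
        return tuple(sorted({o.term for o in self.observations}))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.observations,
            columns=["patient_id", "arm", "term", "timepoint", "level"],
        )

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, scale: SeverityScale, stage_order: Sequence[str]
    ) -> "ObservationTable":
        obs = tuple(
            Observation(
                str(r.patient_id), str(r.arm), str(r.term), str(r.timepoint), str(r.level)
            )
            for r in df.itertuples(index=False)
        )
        return cls(scale=scale, stage_order=tuple(stage_order), observations=obs)


@dataclass(frozen=True)
class ValidationFinding:
    """One invariant violation, identified by a short code and a record key."""

    code: str
    message: str
    key: tuple

    def __str__(self) -> str:  # pragma: no cover - repr sugar
        return f"[{self.code}] {self.message} (key={self.key})"


def validate_table(table: ObservationTable, strict: bool = False) -> list[ValidationFinding]:
    """Scan a table for invariant violations; findings are data, not errors.

    Checks: at most one observation per (patient, term, timepoint); every
    level in the scale vocabulary; every timepoint in ``stage_order``.
    With ``strict=True`` additionally flags patients who return to an
    on-study state after an explicit missing/off-treatment observation or
    an assessment gap — the missing state is expected to be absorbing but
    this is advisory (flagged, not fatal).
    """
    findings: list[ValidationFinding] = []
    scale = table.scale
    valid_states = set(scale.all_states)
    stage_idx = {s: i for i, s in enumerate(table.stage_order)}

    seen: dict[tuple, Observation] = {}
    for o in table.observations:
        k = (o.patient_id, o.term, o.timepoint)
        if k in seen:
            findings.append(
                ValidationFinding("duplicate-key", "more than one observation", k)
            )
        else:
            seen[k] = o
        if o.level not in valid_states:
            findings.append(
                ValidationFinding("unknown-level", f"level {o.level!r} not in scale", k)
            )
        if o.timepoint not in stage_idx:
            findings.append(
                ValidationFinding(
                    "unknown-timepoint", f"timepoint {o.timepoint!r} not in stage order", k
                )
            )

    if strict:
        by_patient_term: dict[tuple, list[Observation]] = {}
        for o in table.observations:
            if o.timepoint in stage_idx:
                by_patient_term.setdefault((o.patient_id, o.term), []).append(o)
        for (pid, term), obs in by_patient_term.items():
            obs = sorted(obs, key=lambda o: stage_idx[o.timepoint])
            # indices at which the patient is effectively on study
            on_idx = [stage_idx[o.timepoint] for o in obs if o.level != scale.missing_level]
            off_idx = [stage_idx[o.timepoint] for o in obs if o.level == scale.missing_level]
            if not on_idx:
                continue
            resumed = (off_idx and min(off_idx) < max(on_idx)) or (
                # a gap inside the observed span is filled as missing, so a
                # later on-study observation is a resumption
                max(on_idx) - min(on_idx) + 1 > len(set(on_idx) | set(off_idx))
                and any(
                    i not in set(on_idx) | set(off_idx)
                    for i in range(min(on_idx), max(on_idx))
                )
            )
            if resumed:
                findings.append(
                    ValidationFinding(
                        "missing-not-absorbing",
                        "patient resumes an on-study state after going missing/off",
                        (pid, term),
                    )
                )
    return findings


def assert_valid(table: ObservationTable, strict: bool = False) -> None:
    """Raise :class:`ValidationError` if :func:`validate_table` finds anything."""
    findings = validate_table(table, strict=strict)
    if findings:
        raise ValidationError(findings)


@dataclass(frozen=True)
class TrajectoryMatrix:
    """Rectangular per-patient state sequences over an ordered stage window."""

    scale: SeverityScale
    patient_ids: tuple[str, ...]
    stages: tuple[str, ...]
    states: tuple[tuple[str, ...], ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "patient_ids", tuple(self.patient_ids))
        object.__setattr__(self, "stages", tuple(self.stages))
        object.__setattr__(self, "states", tuple(tuple(r) for r in self.states))
        if len(self.states) != len(self.patient_ids):
            raise ValueError("one state row per patient required")
        ns = len(self.stages)
        valid = set(self.scale.all_states)
        for pid, row in zip(self.patient_ids, self.states):
            if len(row) != ns:
                raise ValueError(f"patient {pid!r}: expected {ns} states, got {len(row)}")
            bad = [s for s in row if s not in valid]
            if bad:
                raise ValueError(f"patient {pid!r}: states {bad} not in scale")

    @property
    def n_patients(self) -> int:
        return len(self.patient_ids)

    def row(self, patient_id: str) -> tuple[str, ...]:
        return self.states[self.patient_ids.index(patient_id)]

    def map_states(
        self, mapping: Mapping[str, str], scale: SeverityScale
    ) -> "TrajectoryMatrix":
        """Relabel states (e.g. collapse CTCAE grades 0 and 1 into a "0-1" bin).

        States absent from ``mapping`` are kept as-is; the result is
        validated against the new scale.
        """
        new_states = tuple(
            tuple(mapping.get(s, s) for s in row) for row in self.states
        )
        return TrajectoryMatrix(scale, self.patient_ids, self.stages, new_states)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            list(self.states), index=list(self.patient_ids), columns=list(self.stages)
        )


def _is_contiguous_sublist(sub: Sequence[str], full: Sequence[str]) -> bool:
    if not sub:
        return False
    try:
        start = full.index(sub[0])
    except ValueError:
        return False
    return tuple(full[start : start + len(sub)]) == tuple(sub)


def pivot_trajectories(
    table: ObservationTable,
    term: str,
    arm: str,
    stages: Sequence[str] | None = None,
) -> TrajectoryMatrix:
    """Pivot long-format observations into a rectangular trajectory matrix.

    Includes every patient in ``arm`` with at least one observation of
    ``term`` inside the stage window; absent (patient, stage) cells are
    filled with the scale's missing level. Duplicate cells resolve to the
    most severe level (use :func:`validate_table` to detect them).

    Raises
    ------
    NoMatchingRecordsError
        If the term or arm does not occur in the table at all — distinct
        from an empty-but-valid stage selection.
    ValueError
        If ``stages`` is empty or not a contiguous run of the table's
        stage order.
    """
    if stages is None:
        stages = table.stage_order
    stages = tuple(stages)
    if not stages:
        raise ValueError("stage window must contain at least one stage")
    if not _is_contiguous_sublist(stages, table.stage_order):
        raise ValueError(f"stages {stages} are not a contiguous run of the stage order")

    if term not in table.terms():
        raise NoMatchingRecordsError(f"no records for term {term!r}")
    if arm not in table.arms():
        raise NoMatchingRecordsError(f"no records for arm {arm!r}")

    scale = table.scale
    sev = {lv: i for i, lv in enumerate(scale.all_states)}
    cells: dict[str, dict[str, str]] = {}
    in_window = set(stages)
    for o in table.observations:
        if o.term != term or o.arm != arm or o.timepoint not in in_window:
            continue
        row = cells.setdefault(o.patient_id, {})
        prev = row.get(o.timepoint)
        if prev is None or sev.get(o.level, -1) > sev.get(prev, -1):
            row[o.timepoint] = o.level
    pids = tuple(sorted(cells))
    states = tuple(
        tuple(cells[pid].get(st, scale.missing_level) for st in stages) for pid in pids
    )
    return TrajectoryMatrix(scale=scale, patient_ids=pids, stages=stages, states=states)
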