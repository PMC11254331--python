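"""Reading and writing tolerability tables.

Two on-disk dialects are supported, both UTF-8 CSV with a header row and
RFC-4180 quoting:

* the **canonical** long format with fixed columns
  ``patient_id, arm, term, timepoint, level`` (:func:`read_table` /
  :func:`write_table`), and
* the **custom upload** format of the interactive explorers: three
  user-named columns — patient identifier, time point, and the
  symptom/response of interest — plus a user-declared ordering of time
  points and response levels (:func:`read_custom_table` /
  :func:`write_custom_table`). The symptom term is taken from the
  response column's header name. An optional arm column lets multi-arm
  tables round-trip through this format.

Design notes: ordering of time points and responses is always an
explicit user declaration, never inferred from the file; blank response
cells map to the missing label (the "No Response" category exists for
exactly this), they do not error.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .data_model import Observation, ObservationTable, SeverityScale
from .errors import DuplicateRecordError, SchemaError, UnknownLabelError

__all__ = [
    "ColumnMapping",
    "read_custom_table",
    "write_custom_table",
    "canonical_mapping",
    "load_mapping",
    "save_mapping",
    "read_table",
    "write_table",
]

CANONICAL_COLUMNS = ("patient_id", "arm", "term", "timepoint", "level")


@dataclass(frozen=True)
class ColumnMapping:
    """Declares which columns hold what, and the time/response orderings."""

    id_column: str
    time_column: str
    response_column: str
    time_order: tuple[str, ...]
    response_order: tuple[str, ...]
    arm_column: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "time_order", tuple(self.time_order))
        object.__setattr__(self, "response_order", tuple(self.response_order))
        names = [self.id_column, self.time_column, self.response_column]
        if self.arm_column is not None:
            names.append(self.arm_column)
        if len(set(names)) != len(names):
            raise SchemaError(f"mapped column names must be distinct, got {names}")
        if len(set(self.time_order)) != len(self.time_order):
            raise SchemaError("time_order entries must be unique")
        if len(set(self.response_order)) != len(self.response_order):
            raise SchemaError("response_order entries must be unique")

    def to_dict(self) -> dict:
        d = {
            "id_column": self.id_column,
            "time_column": self.time_column,
            "response_column": self.response_column,
            "time_order": list(self.time_order),
            "response_order": list(self.response_order),
        }
        if self.arm_column is not None:
            d["arm_column"] = self.arm_column
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "ColumnMapping":
        return cls(
            id_column=d["id_column"],
            time_column=d["time_column"],
            response_column=d["response_column"],
            time_order=tuple(d["time_order"]),
            response_order=tuple(d["response_order"]),
            arm_column=d.get("arm_column"),
        )


def save_mapping(mapping: ColumnMapping, missing_label: str, path) -> None:
    """Write a mapping plus its missing label as a JSON config file."""
    d = mapping.to_dict()
    d["missing_label"] = missing_label
    Path(path).write_text(json.dumps(d, indent=2, sort_keys=True) + "\n", encoding="utf-8")


def load_mapping(path) -> tuple[ColumnMapping, str]:
    """Read a JSON mapping config; returns (mapping, missing_label)."""
    d = json.loads(Path(path).read_text(encoding="utf-8"))
    try:
        missing = d["missing_label"]
    except KeyError as exc:
        raise SchemaError("mapping file lacks the missing_label key") from exc
    return ColumnMapping.from_dict(d), str(missing)


def _read_csv(path, delimiter: str) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed delimited text
        raise SchemaError(f"cannot parse {path}: {exc}") from exc


def read_custom_table(
    path,
    mapping: ColumnMapping,
    missing_label: str,
    *,
    scale: SeverityScale | None = None,
    delimiter: str = ",",
    strict: bool = True,
) -> ObservationTable:
    """Read an explorer-style upload into an :class:`ObservationTable`.

    The resulting scale's levels are ``mapping.response_order`` with
    ``missing_label`` as the missing level (pass ``scale`` to attach a
    richer scale, e.g. one carrying grade values; its levels must match).
    Stage order is ``mapping.time_order``; the term is the response
    column's header name.

    With ``strict=True`` a duplicate (patient, time) pair raises; in
    lenient mode the most severe response wins, with a warning.
    """
    if scale is None:
        scale = SeverityScale(
            name=mapping.response_column,
            levels=mapping.response_order,
            missing_level=missing_label,
        )
    else:
        if tuple(scale.levels) != tuple(mapping.response_order):
            raise SchemaError("provided scale levels do not match response_order")
        if scale.missing_level != missing_label:
            raise SchemaError("provided scale missing level does not match missing_label")

    df = _read_csv(path, delimiter)
    needed = [mapping.id_column, mapping.time_column, mapping.response_column]
    if mapping.arm_column is not None:
        needed.append(mapping.arm_column)
    for col in needed:
        if col not in df.columns:
            raise SchemaError(f"input file lacks mapped column {col!r}")

    time_set = set(mapping.time_order)
    level_set = set(mapping.response_order)
    sev = {lv: i for i, lv in enumerate(scale.all_states)}
    term = mapping.response_column

    best: dict[tuple[str, str], str] = {}
    arm_of: dict[tuple[str, str], str] = {}
    cols = list(df.columns)
    for i, vals in enumerate(df.itertuples(index=False, name=None), start=2):  # header is line 1
        rec = dict(zip(cols, vals))
        pid = str(rec[mapping.id_column])
        t = str(rec[mapping.time_column])
        resp = str(rec[mapping.response_column]).strip()
        if t not in time_set:
            raise UnknownLabelError(
                f"line {i}: time point {t!r} not in the declared time order"
            )
        if resp == "":
            resp = missing_label
        elif resp != missing_label and resp not in level_set:
            raise UnknownLabelError(
                f"line {i}: response {resp!r} not in the declared response order"
            )
        arm = str(rec[mapping.arm_column]) if mapping.arm_column is not None else "all"
        key = (pid, t)
        if key in best:
            if strict:
                raise DuplicateRecordError(
                    f"line {i}: duplicate observation for patient {pid!r} at {t!r}"
                )
            if sev[resp] > sev[best[key]]:
                best[key] = resp
                arm_of[key] = arm
            warnings.warn(
                f"duplicate ({pid!r}, {t!r}) resolved to most severe level",
                stacklevel=2,
            )
        else:
            best[key] = resp
            arm_of[key] = arm

    obs = tuple(
        Observation(pid, arm_of[(pid, t)], term, t, lv) for (pid, t), lv in best.items()
    )
    return ObservationTable(scale=scale, stage_order=mapping.time_order, observations=obs)


def canonical_mapping(table: ObservationTable) -> ColumnMapping:
    """The mapping :func:`write_custom_table` uses for a given table."""
    terms = table.terms()
    term = terms[0] if terms else "response"
    return ColumnMapping(
        id_column="patient_id",
        time_column="time_point",
        response_column=term,
        time_order=table.stage_order,
        response_order=table.scale.levels,
        arm_column="arm",
    )


def write_custom_table(table: ObservationTable, path, *, delimiter: str = ",") -> ColumnMapping:
    """Write a single-term table in the custom upload format.

    Returns the :class:`ColumnMapping` under which
    :func:`read_custom_table` reproduces the table exactly.
    """
    terms = table.terms()
    if len(terms) > 1:
        raise SchemaError(
            f"custom format holds one term per file; table has {len(terms)}: {terms}"
        )
    mapping = canonical_mapping(table)
    reserved = {mapping.id_column, mapping.time_column, mapping.arm_column}
    if mapping.response_column in reserved:
        raise SchemaError(
            f"term {mapping.response_column!r} collides with a reserved column name"
        )
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter=delimiter)
        w.writerow(
            [mapping.id_column, mapping.arm_column, mapping.time_column, mapping.response_column]
        )
        for o in table.observations:
            w.writerow([o.patient_id, o.arm, o.timepoint, o.level])
    return mapping


def read_table(path, scale: SeverityScale, stage_order: Sequence[str]) -> ObservationTable:
    """Read the canonical five-column long format."""
    df = _read_csv(path, ",")
    for col in CANONICAL_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"input file lacks canonical column {col!r}")
    return ObservationTable.from_frame(df[list(CANONICAL_COLUMNS)], scale, stage_order)


def write_table(table: ObservationTable, path) -> None:
    """Write the canonical five-column long format."""
    table.to_frame().to_csv(path, index=False)
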