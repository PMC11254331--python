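"""The Toxicity Index (TI): an order-preserving scalar toxicity summary.

A patient's toxicity profile over a treatment course is a multiset of
per-cycle grades w. With the grades sorted in descending order
w(1) >= w(2) >= ... >= w(n),

    TI = sum_i  w(i) * prod_{j<i} (1 + w(j))^{-1}

The leading term is the maximum grade m; every further grade adds a
successively discounted amount, so m <= TI < m + 1: the integer part of
the TI is the worst grade and the fractional part encodes how much of
the rest of the course was also toxic. For CTCAE grades 0..5 the TI
therefore lives in [0, 6) — it can approach but never reach 6.

Properties (all exercised by the test suite):
  * permutation-invariant in the input order;
  * appending a grade of 0 changes nothing; appending g > 0 strictly
    increases the TI;
  * profiles are ordered first by maximum grade, then lexicographically
    by the remaining sorted grades.

Missing or off-treatment cycles contribute no grade: they are skipped,
never imputed as grade 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .data_model import SeverityScale, TrajectoryMatrix
from .errors import ConfigurationError

__all__ = ["toxicity_index", "grades_from_states", "TISummary", "cohort_ti_summary"]

#: TI histogram bin edges: width 0.5 across the full [0, 6) range.
TI_BIN_EDGES = tuple(np.arange(0.0, 6.0 + 1e-9, 0.5))

GRADE_MIN, GRADE_MAX = 0.0, 5.0


def toxicity_index(grades: Iterable[float]) -> float:
    """Toxicity Index of a multiset of grades (empty profile -> 0.0).

    Raises :class:`ValueError` for grades outside [0, 5].
    """
    g = sorted((float(x) for x in grades), reverse=True)
    for x in g:
        if not math.isfinite(x) or x < GRADE_MIN or x > GRADE_MAX:
            raise ValueError(f"grade {x} outside the [0, 5] domain")
    ti = 0.0
    denom = 1.0
    for w in g:
        ti += w / denom
        denom *= 1.0 + w
    return ti


def grades_from_states(
    states: Sequence[str], scale: SeverityScale
) -> list[float]:
    """Map a state sequence to its grade profile, skipping the missing level."""
    if scale.grade_values is None:
        raise ConfigurationError(
            f"scale {scale.name!r} has no grade values; TI is undefined for it"
        )
    return [scale.grade_values[s] for s in states if s != scale.missing_level]


@dataclass(frozen=True)
class TISummary:
    """Distribution of per-patient TI values within a cohort.

    ``sd`` is the sample standard deviation (n - 1 denominator) and is
    ``None`` — never 0 — when only one patient is present. Quartiles use
    linear interpolation between order statistics (the "type 7" rule).
    """

    values: tuple[float, ...]
    mean: float
    sd: float | None
    median: float
    q1: float
    q3: float
    bin_edges: tuple[float, ...]
    bin_counts: tuple[int, ...]

    def to_dict(self) -> dict:
        return {
            "values": list(self.values),
            "mean": self.mean,
            "sd": self.sd,
            "median": self.median,
            "q1": self.q1,
            "q3": self.q3,
            "bin_edges": list(self.bin_edges),
            "bin_counts": list(self.bin_counts),
        }


def cohort_ti_summary(
    trajectories: TrajectoryMatrix, scale: SeverityScale | None = None
) -> TISummary:
    """Per-patient TI over a trajectory matrix, with summary statistics.

    Each patient's profile is the grades of their non-missing states in
    the matrix window (one term, one cohort). Requires a scale with
    grade values.
    """
    if scale is None:
        scale = trajectories.scale
    if trajectories.n_patients == 0:
        raise ValueError("cannot summarise an empty cohort")
    values = tuple(
        toxicity_index(grades_from_states(row, scale)) for row in trajectories.states
    )
    arr = np.asarray(values, dtype=float)
    counts, _ = np.histogram(arr, bins=np.asarray(TI_BIN_EDGES))
    q1, med, q3 = np.percentile(arr, [25.0, 50.0, 75.0])
    return TISummary(
        values=values,
        mean=float(arr.mean()),
        sd=float(arr.std(ddof=1)) if arr.size > 1 else None,
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        bin_edges=TI_BIN_EDGES,
        bin_counts=tuple(int(c) for c in counts),
    )
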