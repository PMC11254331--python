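"""Synthetic longitudinal trial generator.

The trials this library was designed around are not publicly deposited,
so every analysis here is exercised on synthetic extracts with the same
structure: two or three treatment arms, an ordered severity scale with a
terminal off-study category, and assessments on a fixed cycle grid.

Each patient's state sequence is a first-order Markov chain: the first
stage is drawn from a per-arm initial distribution over the ordinary
severity levels, and each subsequent stage from a per-arm transition
matrix over levels plus the missing/off-study state. By default the
missing state is absorbing — once a patient goes off study they stay
off — and stages spent in it produce *no stored observation*, so the
downstream missing-cell fill rule is exercised by construction.

Two preset specifications ship with the package:

* ``b35-ae`` — a two-arm endocrine-therapy trial assessed by CTCAE
  grade (raw grades 0..5 stored; the "0-1" display bin is applied at
  presentation time) every 6 months from 6 to 60 months;
* ``b30-pro`` — a three-arm chemotherapy trial with BCPT-style
  patient-reported bother levels at baseline, day 1 of cycle 4, and
  6-month follow-ups to 24 months;
* ``b35-pro`` — the two-arm trial's patient-reported companion, baseline
  plus 6-month assessments to 60 months.

Transition kernels are simple ordinal random walks: a large
stay-in-place mass, a bias toward improvement over time, a smaller
worsening mass, and a per-cycle absorbing dropout hazard. Arms differ
mildly in their worsening/dropout rates. The exact numbers are package
defaults chosen to look like a tolerable oral regimen; they are
documented in docs/methods.md and are fully overridable through
:class:`MarkovSpec`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .data_model import Observation, ObservationTable, SeverityScale, pivot_trajectories
from .errors import ConfigurationError, NoMatchingRecordsError

__all__ = [
    "MarkovSpec",
    "simulate_trial",
    "TransitionEstimate",
    "estimate_transitions",
    "ctcae_scale",
    "ctcae_display_scale",
    "CTCAE_DISPLAY_MAP",
    "bcpt_scale",
    "preset",
    "PRESETS",
]

_PROB_TOL = 1e-9


def ctcae_scale() -> SeverityScale:
    """CTCAE adverse-event grades 0..5 with "Off Treatment" as missing."""
    return SeverityScale(
        name="CTCAE",
        levels=("0", "1", "2", "3", "4", "5"),
        missing_level="Off Treatment",
        grade_values={str(g): float(g) for g in range(6)},
    )


#: Display mapping that collapses raw grades 0 and 1 into the "0-1" bin.
CTCAE_DISPLAY_MAP = {"0": "0-1", "1": "0-1"}


def ctcae_display_scale() -> SeverityScale:
    """CTCAE display scale with the 0-1 bin (used for figures/summaries)."""
    return SeverityScale(
        name="CTCAE (display)",
        levels=("0-1", "2", "3", "4", "5"),
        missing_level="Off Treatment",
        grade_values={"0-1": 1.0, "2": 2.0, "3": 3.0, "4": 4.0, "5": 5.0},
    )


def bcpt_scale() -> SeverityScale:
    """BCPT symptom-checklist bother levels with "No Response" as missing."""
    return SeverityScale(
        name="BCPT",
        levels=("Not at all", "Slightly", "Moderately", "Quite a bit", "Extremely"),
        missing_level="No Response",
    )


@dataclass(frozen=True)
class MarkovSpec:
    """Per-arm first-order Markov specification of a synthetic trial.

    ``initial_dist[arm]`` is a probability vector over the scale's
    ordinary levels; ``transition[arm]`` is a row-stochastic matrix over
    levels + missing level (the last row/column is the missing state).
    """

    scale: SeverityScale
    arms: tuple[str, ...]
    initial_dist: Mapping[str, tuple[float, ...]]
    transition: Mapping[str, tuple[tuple[float, ...], ...]]
    stages: tuple[str, ...]
    dropout_absorbing: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "arms", tuple(self.arms))
        object.__setattr__(self, "stages", tuple(self.stages))
        k = len(self.scale.levels)
        m = k + 1  # + missing state
        if len(self.stages) < 2:
            raise ConfigurationError("a trial needs at least two stages")
        if not self.arms:
            raise ConfigurationError("a trial needs at least one arm")
        init = {}
        trans = {}
        for arm in self.arms:
            if arm not in self.initial_dist or arm not in self.transition:
                raise ConfigurationError(f"arm {arm!r} lacks initial_dist or transition")
            p = tuple(float(x) for x in self.initial_dist[arm])
            if len(p) != k:
                raise ConfigurationError(
                    f"arm {arm!r}: initial_dist has {len(p)} entries, expected {k}"
                )
            _check_prob_vector(p, f"initial_dist[{arm!r}]")
            P = tuple(tuple(float(x) for x in row) for row in self.transition[arm])
            if len(P) != m or any(len(row) != m for row in P):
                raise ConfigurationError(
                    f"arm {arm!r}: transition must be {m}x{m} (levels + missing)"
                )
            for i, row in enumerate(P):
                _check_prob_vector(row, f"transition[{arm!r}] row {i}")
            if self.dropout_absorbing:
                last = P[-1]
                if abs(last[-1] - 1.0) > _PROB_TOL or any(
                    x > _PROB_TOL for x in last[:-1]
                ):
                    raise ConfigurationError(
                        f"arm {arm!r}: dropout_absorbing requires the missing-state "
                        "row to be the unit vector on the missing state"
                    )
            init[arm] = p
            trans[arm] = P
        object.__setattr__(self, "initial_dist", init)
        object.__setattr__(self, "transition", trans)

    def to_dict(self) -> dict:
        return {
            "scale": self.scale.to_dict(),
            "arms": list(self.arms),
            "initial_dist": {a: list(v) for a, v in self.initial_dist.items()},
            "transition": {a: [list(r) for r in m] for a, m in self.transition.items()},
            "stages": list(self.stages),
            "dropout_absorbing": self.dropout_absorbing,
        }

    def save(self, path) -> None:
        Path(path).write_text(
            json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )

    @classmethod
    def from_dict(cls, d: Mapping) -> "MarkovSpec":
        return cls(
            scale=SeverityScale.from_dict(d["scale"]),
            arms=tuple(d["arms"]),
            initial_dist={a: tuple(v) for a, v in d["initial_dist"].items()},
            transition={
                a: tuple(tuple(r) for r in m) for a, m in d["transition"].items()
            },
            stages=tuple(d["stages"]),
            dropout_absorbing=bool(d.get("dropout_absorbing", True)),
        )

    @classmethod
    def load(cls, path) -> "MarkovSpec":
        return cls.from_dict(json.loads(Path(path).read_text(encoding="utf-8")))


def _check_prob_vector(p: Sequence[float], what: str) -> None:
    if any(x < 0 for x in p):
        raise ConfigurationError(f"{what}: negative probability")
    if abs(sum(p) - 1.0) > _PROB_TOL:
        raise ConfigurationError(f"{what}: probabilities sum to {sum(p)!r}, not 1")


def _ordinal_kernel(
    k: int, stay: float, improve: float, worsen: float, dropout: float
) -> tuple[tuple[float, ...], ...]:
    """Adjacent-state ordinal random-walk kernel over k levels + absorbing missing.

    From level i: move down one level w.p. ``improve``, up one w.p.
    ``worsen``, to the missing state w.p. ``dropout``, stay otherwise;
    boundary moves fold back into staying. Rows sum to 1 exactly.
    """
    if min(stay, improve, worsen, dropout) < 0 or stay + improve + worsen + dropout > 1 + _PROB_TOL:
        raise ConfigurationError("kernel masses must be non-negative and sum to <= 1")
    m = k + 1
    rows = []
    for i in range(k):
        row = [0.0] * m
        down = improve if i > 0 else 0.0
        up = worsen if i < k - 1 else 0.0
        row[i] = 1.0 - down - up - dropout
        if i > 0:
            row[i - 1] = down
        if i < k - 1:
            row[i + 1] = up
        row[-1] = dropout
        rows.append(tuple(row))
    rows.append(tuple([0.0] * k + [1.0]))  # absorbing missing state
    return tuple(rows)


def _b35_ae_preset() -> MarkovSpec:
    scale = ctcae_scale()
    arms = ("anastrozole", "tamoxifen")
    # aromatase inhibition is the more arthralgia-prone arm: slightly more
    # initial burden, worsening and dropout
    init = {
        "anastrozole": (0.44, 0.24, 0.17, 0.10, 0.04, 0.01),
        "tamoxifen": (0.52, 0.24, 0.14, 0.07, 0.02, 0.01),
    }
    trans = {
        "anastrozole": _ordinal_kernel(6, stay=0.58, improve=0.22, worsen=0.10, dropout=0.07),
        "tamoxifen": _ordinal_kernel(6, stay=0.60, improve=0.24, worsen=0.07, dropout=0.06),
    }
    stages = tuple(f"{m} mo" for m in range(6, 66, 6))
    return MarkovSpec(scale=scale, arms=arms, initial_dist=init, transition=trans, stages=stages)


def _b30_pro_preset() -> MarkovSpec:
    scale = bcpt_scale()
    arms = ("sequential ACT", "AT", "concurrent ACT")
    init = {
        "sequential ACT": (0.50, 0.25, 0.15, 0.07, 0.03),
        "AT": (0.48, 0.26, 0.16, 0.07, 0.03),
        "concurrent ACT": (0.45, 0.26, 0.17, 0.08, 0.04),
    }
    trans = {
        "sequential ACT": _ordinal_kernel(5, stay=0.55, improve=0.20, worsen=0.15, dropout=0.08),
        "AT": _ordinal_kernel(5, stay=0.55, improve=0.19, worsen=0.16, dropout=0.08),
        "concurrent ACT": _ordinal_kernel(5, stay=0.53, improve=0.18, worsen=0.18, dropout=0.09),
    }
    stages = (
        "Baseline",
        "Cycle 4 Day 1",
        "6-month follow-up",
        "12-month follow-up",
        "18-month follow-up",
        "24-month follow-up",
    )
    return MarkovSpec(scale=scale, arms=arms, initial_dist=init, transition=trans, stages=stages)


def _b35_pro_preset() -> MarkovSpec:
    scale = bcpt_scale()
    arms = ("anastrozole", "tamoxifen")
    init = {
        "anastrozole": (0.42, 0.27, 0.18, 0.09, 0.04),
        "tamoxifen": (0.38, 0.26, 0.21, 0.10, 0.05),
    }
    trans = {
        "anastrozole": _ordinal_kernel(5, stay=0.58, improve=0.20, worsen=0.14, dropout=0.05),
        "tamoxifen": _ordinal_kernel(5, stay=0.58, improve=0.19, worsen=0.15, dropout=0.05),
    }
    stages = ("Baseline",) + tuple(f"{m} mo" for m in range(6, 66, 6))
    return MarkovSpec(scale=scale, arms=arms, initial_dist=init, transition=trans, stages=stages)


PRESETS = {
    "b35-ae": _b35_ae_preset,
    "b30-pro": _b30_pro_preset,
    "b35-pro": _b35_pro_preset,
}

#: Default symptom term simulated for each preset.
PRESET_TERMS = {
    "b35-ae": "arthralgia",
    "b30-pro": "numbness and tingling",
    "b35-pro": "hot flashes",
}


def preset(name: str) -> MarkovSpec:
    """Return a fresh copy of a named preset specification."""
    try:
        return PRESETS[name]()
    except KeyError:
        raise ConfigurationError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        ) from None


def simulate_trial(
    spec: MarkovSpec, n_per_arm: int, term: str = "symptom", seed: int = 0
) -> ObservationTable:
    """Simulate a trial extract: ``n_per_arm`` patients per arm.

    Stages where a patient sits in the missing state are *not* stored, so
    the table exercises the downstream fill rule. Identical
    (spec, n_per_arm, term, seed) inputs give identical tables.
    """
    if n_per_arm < 1:
        raise ConfigurationError("n_per_arm must be >= 1")
    rng = np.random.default_rng(seed)
    scale = spec.scale
    k = len(scale.levels)
    states_all = scale.all_states  # levels + missing, index k = missing
    obs: list[Observation] = []
    width = max(4, len(str(n_per_arm)))
    for arm in spec.arms:
        init = np.asarray(spec.initial_dist[arm], dtype=float)
        P = np.asarray(spec.transition[arm], dtype=float)
        pids = [f"{arm}-{i + 1:0{width}d}" for i in range(n_per_arm)]
        cur = rng.choice(k, size=n_per_arm, p=init / init.sum())
        seqs = np.empty((n_per_arm, len(spec.stages)), dtype=int)
        seqs[:, 0] = cur
        for j in range(1, len(spec.stages)):
            nxt = np.empty(n_per_arm, dtype=int)
            for s in range(k + 1):
                idx = np.flatnonzero(cur == s)
                if idx.size:
                    nxt[idx] = rng.choice(k + 1, size=idx.size, p=P[s] / P[s].sum())
            cur = nxt
            seqs[:, j] = cur
        for pid, row in zip(pids, seqs):
            for stage, s in zip(spec.stages, row):
                if s == k:  # missing state: no stored observation
                    continue
                obs.append(Observation(pid, arm, term, stage, states_all[s]))
    return ObservationTable(scale=scale, stage_order=spec.stages, observations=tuple(obs))


@dataclass(frozen=True)
class TransitionEstimate:
    """Row-normalised transition counts; unobserved source states flagged.

    ``matrix[i][j]`` estimates P(state j at the next stage | state i now)
    over the scale's levels + missing state. Rows for states never
    observed as a transition source are NaN and listed in ``unobserved``
    — they are flagged, never fabricated.
    """

    states: tuple[str, ...]
    matrix: np.ndarray
    counts: np.ndarray
    unobserved: tuple[str, ...]

    def max_abs_error(self, reference: Sequence[Sequence[float]]) -> float:
        """Largest |estimate - reference| over the observed rows."""
        ref = np.asarray(reference, dtype=float)
        obs_rows = ~np.isnan(self.matrix).all(axis=1)
        return float(np.max(np.abs(self.matrix[obs_rows] - ref[obs_rows])))


def estimate_transitions(table: ObservationTable, term: str, arm: str) -> TransitionEstimate:
    """Estimate the one-step transition matrix from an observed table.

    Trajectories are pivoted over the full stage order (absent cells
    filled with the missing state, matching how the data would be
    displayed) and consecutive-stage pairs tallied.
    """
    traj = pivot_trajectories(table, term, arm)
    if len(traj.stages) < 2:
        raise NoMatchingRecordsError("need at least two stages to estimate transitions")
    states = table.scale.all_states
    index = {s: i for i, s in enumerate(states)}
    m = len(states)
    counts = np.zeros((m, m), dtype=np.int64)
    for row in traj.states:
        for a, b in zip(row, row[1:]):
            counts[index[a], index[b]] += 1
    totals = counts.sum(axis=1)
    matrix = np.full((m, m), np.nan)
    nz = totals > 0
    matrix[nz] = counts[nz] / totals[nz, None]
    unobserved = tuple(s for s, t in zip(states, totals) if t == 0)
    return TransitionEstimate(states=states, matrix=matrix, counts=counts, unobserved=unobserved)
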