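# Methods

## Data model

An `ObservationTable` is a long-format set of observations — one
severity level per (patient, arm, term, timepoint) — governed by a
single `SeverityScale`: an ordered list of levels (least to most severe)
plus one designated *missing level* that is not an ordinary level but an
appended terminal display category. Two scales ship as constructors:
CTCAE grades `"0"`–`"5"` with `"Off Treatment"` (and numeric grade
values 0–5), and the BCPT bother levels `"Not at all"` … `"Extremely"`
with `"No Response"` (no grade values; the Toxicity Index is undefined
for it and requesting it raises a configuration error).

Raw CTCAE grades are stored; the familiar `"0-1"` bin is a *display
mapping* (`CTCAE_DISPLAY_MAP` + `TrajectoryMatrix.map_states`) applied
at flow/summary time, so the Toxicity Index always sees raw grades.

Pivoting (`pivot_trajectories`) produces a rectangular
`TrajectoryMatrix`: one state per patient per stage for one (term, arm),
restricted to a contiguous stage window. **Fill rule:** any absent
(patient, stage) cell becomes the missing level. The alternatives —
dropping the patient, or carrying the last observation forward — either
shrink the cohort silently or invent data; making absence an explicit
category keeps the Sankey truthful about attrition. Patients with *no*
observation of the term in the window are excluded entirely (they were
never in this cohort), which is why a matrix's row count can be below
the table's patient count.

Validation is data, not exceptions: `validate_table` returns findings
(duplicate keys, unknown levels, unknown timepoints), and `assert_valid`
is the raising wrapper. Whether the missing state is absorbing (once off
treatment, always off) is a property of the trial, not of the format, so
a return from the missing state — including a gap between assessments,
which the fill rule turns into a round trip through the missing
category — is flagged only under `strict=True` and is never fatal.
Duplicate (patient, term, timepoint) rows are rejected by the strict
ingest path and resolved to the most severe level (with a warning) in
lenient mode, since repeated assessments do occur in real extracts.

## Ingest

The custom upload schema is three user-named columns — patient
identifier, time point, response — with the symptom term taken from the
response column's header, plus an explicit, user-declared ordering of
time points and of responses. Nothing is inferred from file contents;
the `ColumnMapping` (serialisable as a small JSON config with a
`missing_label`) is the whole contract. Although such uploads are often
described as "wide", the operational description — the patient
identifier repeated once per time point — is long format, and that is
what is implemented. Blank response cells map to the missing label
rather than erroring; that is precisely what a "No Response" category is
for. A CSV cell value equal to the missing label is also accepted.

The three-column schema cannot carry a treatment arm, so
`write_custom_table` adds an optional arm column (declared in the
mapping) and `read_custom_table` defaults absent arms to `"all"`. This
keeps the round-trip identity — write → read reproduces the table
exactly, including multi-arm synthetic tables — which is property-tested
across seeds and across adversarial labels (embedded commas, quotes,
newlines; RFC-4180 quoting via the standard csv/pandas machinery).

## Toxicity Index

With a patient's grades sorted descending, w(1) ≥ … ≥ w(n):

    TI = Σ_{i=1..n} w(i) · Π_{j<i} (1 + w(j))^{-1}

Properties relied on (and tested exhaustively over all grade sequences
of length ≤ 6): TI is permutation-invariant; an empty or all-zero
profile gives 0; appending a 0 changes nothing and appending g > 0
strictly increases it; and max-grade bands never overlap —
m ≤ TI < m + 1 — so the supremum for grades ≤ 5 is 6, approached but
never attained (the length-6 all-grade-5 profile reaches
6·(1 − 6⁻⁶) ≈ 5.99987).

Decisions:

* **Inputs per patient** are the per-cycle grades of the *single
  selected term* inside the selected window — matching how a cohort is
  defined — not a pool across terms. This is an interpretation (the
  per-term reading of the cohort workflow); computing a cross-term TI is
  possible by concatenating `grades_from_states` outputs.
* **Missing cycles contribute no grade.** Off-treatment is absence of
  assessment, not grade 0; imputing 0 would conflate recovery with
  attrition.
* **Summary statistics:** sample SD (n − 1), reported as unavailable —
  never 0 — for a single patient; quartiles by linear interpolation
  between order statistics (numpy's default, the "type 7" rule), the
  common convention where none is otherwise specified.
* **Histogram bins:** fixed width 0.5 over [0, 6), so bins align with
  the half-open max-grade bands and histograms are comparable across
  cohorts.

## Flow graphs

`build_flow_graph` tallies marginal state frequencies per stage (nodes)
and joint frequencies of consecutive-stage state pairs (links). Three
conservation identities hold by construction and are re-checkable via
`check_conservation`: stage totals equal the cohort size, and each
node's outflow and inflow equal its count. The implementation is checked
against an independent pandas `value_counts`/`groupby` tally on hundreds
of randomised matrices. A single-stage matrix is an error (no flows are
definable), as is an empty cohort.

Rendering decisions: nodes are stacked most-severe at top, least at
bottom, missing level pinned last; zero-count nodes are omitted from the
figure but retained with count 0 in the serialised JSON so downstream
consumers always see the full scale; colours come from a fixed
colormap indexed by level position (missing level grey), so palettes are
stable across figures; SVG is the canonical target and is
byte-deterministic (fixed hash salt, no timestamp metadata, text kept as
text), with PNG and standalone HTML as conversions. Node and band
elements carry `id` attributes so tests inspect geometry without image
parsing.

## Cohort summaries

`select_cohort` returns exactly the patients of an arm whose (filled)
state for the term at the start stage equals the chosen initial level,
clipped to the window; zero matches is an empty matrix, not an error,
and the window must span ≥ 2 stages. `final_state_summary` tallies
last-stage states; percentages are rounded half away from zero against
the **initial cohort size** (patients off treatment stay in the
denominator) and are not force-balanced, so rendered percents can sum to
99 or 101. Categories are listed in descending count order, ties broken
most severe first. `grade_duration` distributes each state's occurrences
over the window's stages, counting patient-stage *cells* (a patient at
grade 3 in two cycles is two grade-3 cases); the missing level is
excluded by default with a flag to include it.

## Synthetic trials

The generator emulates the structure of longitudinal trial extracts:
per-arm first-order Markov chains over the scale's levels plus the
missing state, on a fixed stage grid, with the missing state absorbing
by default and never stored as an observation (so the fill rule is
exercised everywhere). One explicit `numpy` generator seeds all
randomness; patient and arm order are deterministic, so identical
(spec, n, term, seed) gives byte-identical CSVs.

Preset parameters (not taken from any published fit — the real datasets
are not public): ordinal adjacent-state kernels with stay probability
0.53–0.60, an improvement bias (improve 0.18–0.25 vs worsen 0.07–0.18)
and a 5–9 % per-cycle absorbing dropout hazard, with the endocrine-arm
preset slightly more arthralgia-prone than its comparator; initial
distributions concentrate on the low grades. These produce cohorts whose
attrition (~half off treatment by 60 months at ~6 %/cycle) and severity
mix look like a tolerable oral regimen. What the generator does *not*
emulate: semi-Markov sojourn times, covariate- or history-dependent
transitions, between-term correlation within a patient, informative
(toxicity-driven) dropout, and measurement error. Tests passing on this
generator therefore demonstrate correctness of the *bookkeeping and
statistics*, not clinical realism of any particular trajectory
distribution.

`estimate_transitions` row-normalises consecutive-stage transition
counts (including filled missing cells); rows for states never observed
as a source are NaN and flagged, never fabricated. Parameter recovery —
max absolute error < 0.03 at 5 000 patients per arm, error shrinking as
n grows — is the generator's own correctness check.

## Problem sizes and numerics

The test suite uses cohorts of 1–400 patients and transition-recovery
runs at 4 000–5 000 patients per arm; the exhaustive TI check enumerates
all 55,986 grade sequences of length ≤ 6. These sizes make every
property either exact (conservation, rounding, round-trips, bounds) or
estimable well inside its tolerance (binomial SE ≈ 0.006 at n = 5 000),
while keeping the whole suite in the tens of seconds. Probability
vectors must sum to 1 within 1e-9; TI hand-oracles are asserted to 1e-9;
no other floating-point tolerances are needed because the remaining
quantities are integer counts.

## Known limitations

One scale per table (no mixed CTCAE + PRO tables); no CDISC SDTM/ADaM
parsing; no statistical inference (no arm comparisons, no TI
regressions); no interactive/hosted UI — figures are static SVG/PNG/HTML
with JSON twins; and the per-term TI interpretation noted above.
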