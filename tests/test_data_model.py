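"""Scale/table invariants, validation findings, and trajectory pivoting."""

import pytest

from toxflow import (
    NoMatchingRecordsError,
    Observation,
    ObservationTable,
    SeverityScale,
    ValidationError,
    assert_valid,
    pivot_trajectories,
    read_table,
    validate_table,
    write_table,
)

from conftest import make_matrix


class TestSeverityScale:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(name="x", levels=(), missing_level="NA"),
            dict(name="x", levels=("a", "a"), missing_level="NA"),
            dict(name="x", levels=("a", "b"), missing_level="b"),
            dict(name="x", levels=("a", "b"), missing_level="NA", grade_values={"a": 1}),
            dict(name="x", levels=("a", "b"), missing_level="NA",
                 grade_values={"a": 2, "b": 1}),
            dict(name="x", levels=("a", "b"), missing_level="NA",
                 grade_values={"a": -1, "b": 1}),
        ],
        ids=["empty", "dup-levels", "missing-in-levels", "partial-grades",
             "decreasing-grades", "negative-grade"],
    )
    def test_invalid_scales_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SeverityScale(**kwargs)

    def test_display_order_severe_first_missing_last(self, ae_scale):
        assert ae_scale.display_order == ("5", "4", "3", "2", "1", "0", "Off Treatment")
        assert ae_scale.all_states[-1] == "Off Treatment"


class TestValidateTable:
    def test_well_formed_table_has_no_findings(self, tiny_table):
        assert validate_table(tiny_table) == []
        assert_valid(tiny_table)  # no raise

    def test_duplicate_key_is_found(self, ae_scale):
        obs = (
            Observation("P1", "A", "arthralgia", "6 mo", "2"),
            Observation("P1", "A", "arthralgia", "6 mo", "3"),
        )
        t = ObservationTable(ae_scale, ("6 mo", "12 mo"), obs)
        findings = validate_table(t)
        assert [f.code for f in findings] == ["duplicate-key"]
        assert findings[0].key == ("P1", "arthralgia", "6 mo")
        with pytest.raises(ValidationError):
            assert_valid(t)

    def test_unknown_level_and_timepoint_found_by_scan(self, ae_scale):
        obs = (
            Observation("P1", "A", "arthralgia", "6 mo", "grade 7"),
            Observation("P2", "A", "arthralgia", "99 mo", "2"),
        )
        t = ObservationTable(ae_scale, ("6 mo",), obs)
        codes = sorted(f.code for f in validate_table(t))
        assert codes == ["unknown-level", "unknown-timepoint"]

    def test_strict_mode_flags_return_from_off_treatment(self, ae_scale):
        obs = (
            Observation("P1", "A", "arthralgia", "6 mo", "2"),
            Observation("P1", "A", "arthralgia", "12 mo", "Off Treatment"),
            Observation("P1", "A", "arthralgia", "18 mo", "1"),
        )
        t = ObservationTable(ae_scale, ("6 mo", "12 mo", "18 mo"), obs)
        assert validate_table(t) == []  # advisory only
        assert [f.code for f in validate_table(t, strict=True)] == ["missing-not-absorbing"]

    def test_strict_mode_flags_assessment_gap(self, ae_scale):
        obs = (
            Observation("P1", "A", "arthralgia", "6 mo", "2"),
            Observation("P1", "A", "arthralgia", "18 mo", "1"),
        )
        t = ObservationTable(ae_scale, ("6 mo", "12 mo", "18 mo"), obs)
        assert [f.code for f in validate_table(t, strict=True)] == ["missing-not-absorbing"]


class TestPivotTrajectories:
    def test_absent_cells_filled_with_missing_level(self, tiny_table):
        m = pivot_trajectories(tiny_table, "arthralgia", "A")
        assert m.row("P1") == ("2", "2", "Off Treatment")

    def test_only_patients_with_observations_included(self, tiny_table):
        m = pivot_trajectories(tiny_table, "arthralgia", "A")
        assert m.patient_ids == ("P1", "P2")
        assert m.n_patients == 2

    def test_row_count_bounded_by_distinct_patients(self, tiny_table):
        m = pivot_trajectories(tiny_table, "arthralgia", "A")
        assert m.n_patients <= len(tiny_table.patients())

    def test_empty_stage_window_is_an_error(self, tiny_table):
        with pytest.raises(ValueError, match="at least one stage"):
            pivot_trajectories(tiny_table, "arthralgia", "A", stages=())

    def test_non_contiguous_window_is_an_error(self, tiny_table):
        with pytest.raises(ValueError, match="contiguous"):
            pivot_trajectories(tiny_table, "arthralgia", "A", stages=("6 mo", "18 mo"))

    @pytest.mark.parametrize("term,arm", [("vertigo", "A"), ("arthralgia", "Z")])
    def test_unknown_term_or_arm_is_distinct_error(self, tiny_table, term, arm):
        with pytest.raises(NoMatchingRecordsError):
            pivot_trajectories(tiny_table, term, arm)

    def test_duplicates_resolve_to_most_severe(self, ae_scale):
        obs = (
            Observation("P1", "A", "arthralgia", "6 mo", "1"),
            Observation("P1", "A", "arthralgia", "6 mo", "3"),
            Observation("P1", "A", "arthralgia", "12 mo", "0"),
        )
        t = ObservationTable(ae_scale, ("6 mo", "12 mo"), obs)
        assert pivot_trajectories(t, "arthralgia", "A").row("P1") == ("3", "0")

    def test_pivot_survives_serialization_round_trip(self, tiny_table, tmp_path):
        before = pivot_trajectories(tiny_table, "arthralgia", "A")
        path = tmp_path / "t.csv"
        write_table(tiny_table, path)
        again = read_table(path, tiny_table.scale, tiny_table.stage_order)
        assert again == tiny_table
        assert pivot_trajectories(again, "arthralgia", "A") == before


class TestTrajectoryMatrix:
    def test_ragged_rows_rejected(self, ae_scale):
        with pytest.raises(ValueError, match="expected 2 states"):
            make_matrix(ae_scale, [("2",)], ("6 mo", "12 mo"))

    def test_unknown_states_rejected(self, ae_scale):
        with pytest.raises(ValueError, match="not in scale"):
            make_matrix(ae_scale, [("2", "banana")], ("6 mo", "12 mo"))

    def test_map_states_collapses_levels(self, ae_scale, display_scale):
        m = make_matrix(ae_scale, [("0", "1", "3")], ("a", "b", "c"))
        d = m.map_states({"0": "0-1", "1": "0-1"}, display_scale)
        assert d.states == (("0-1", "0-1", "3"),)
        assert d.scale is display_scale
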