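"""Custom upload schema: column mapping, reading, writing, round trips."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from toxflow import (
    ColumnMapping,
    DuplicateRecordError,
    SchemaError,
    UnknownLabelError,
    bcpt_scale,
    canonical_mapping,
    load_mapping,
    preset,
    read_custom_table,
    save_mapping,
    simulate_trial,
    write_custom_table,
)

TIMES = ("Baseline", "6 mo", "12 mo")
LEVELS = ("Not at all", "Slightly", "Moderately", "Quite a bit", "Extremely")


def make_mapping(**overrides):
    kwargs = dict(
        id_column="patient_id",
        time_column="crs",
        response_column="numb",
        time_order=TIMES,
        response_order=LEVELS,
    )
    kwargs.update(overrides)
    return ColumnMapping(**kwargs)


def write_lines(path, rows):
    path.write_text("\n".join(rows) + "\n", encoding="utf-8")


class TestColumnMapping:
    def test_duplicate_column_names_rejected_before_io(self):
        with pytest.raises(SchemaError, match="distinct"):
            make_mapping(time_column="patient_id")

    @pytest.mark.parametrize("field", ["time_order", "response_order"])
    def test_duplicate_orderings_rejected(self, field):
        with pytest.raises(SchemaError, match="unique"):
            make_mapping(**{field: ("a", "a")})

    def test_mapping_config_round_trip(self, tmp_path):
        m = make_mapping(arm_column="arm")
        save_mapping(m, "No Response", tmp_path / "m.json")
        m2, missing = load_mapping(tmp_path / "m.json")
        assert m2 == m and missing == "No Response"

    def test_mapping_config_requires_missing_label(self, tmp_path):
        (tmp_path / "m.json").write_text('{"id_column": "a"}')
        with pytest.raises(SchemaError, match="missing_label"):
            load_mapping(tmp_path / "m.json")


class TestReadCustomTable:
    def test_reads_every_row_as_one_observation(self, tmp_path):
        path = tmp_path / "in.csv"
        write_lines(path, [
            "patient_id,crs,numb",
            "P1,Baseline,Not at all",
            "P1,6 mo,Slightly",
            "P1,12 mo,Moderately",
            "P2,Baseline,Quite a bit",
            "P2,6 mo,Extremely",
            "P2,12 mo,Moderately",
        ])
        t = read_custom_table(path, make_mapping(), "No Response")
        assert len(t) == 6
        assert t.stage_order == TIMES
        assert t.scale.levels == LEVELS
        assert t.terms() == ("numb",)

    def test_unknown_response_reports_line_number(self, tmp_path):
        path = tmp_path / "in.csv"
        write_lines(path, ["patient_id,crs,numb", "P1,Baseline,Not at all", "P1,6 mo,Maybe"])
        with pytest.raises(UnknownLabelError, match="line 3.*Maybe"):
            read_custom_table(path, make_mapping(), "No Response")

    def test_unknown_timepoint_reports_line_number(self, tmp_path):
        path = tmp_path / "in.csv"
        write_lines(path, ["patient_id,crs,numb", "P1,99 mo,Slightly"])
        with pytest.raises(UnknownLabelError, match="line 2"):
            read_custom_table(path, make_mapping(), "No Response")

    def test_missing_mapped_column_names_it(self, tmp_path):
        path = tmp_path / "in.csv"
        write_lines(path, ["patient_id,time,numb", "P1,Baseline,Slightly"])
        with pytest.raises(SchemaError, match="'crs'"):
            read_custom_table(path, make_mapping(), "No Response")

    def test_blank_response_maps_to_missing_label(self, tmp_path):
        path = tmp_path / "in.csv"
        write_lines(path, ["patient_id,crs,numb", "P1,Baseline,", "P1,6 mo,Slightly"])
        t = read_custom_table(path, make_mapping(), "No Response")
        levels = {o.timepoint: o.level for o in t.observations}
        assert levels["Baseline"] == "No Response"

    def test_duplicate_rows_strict_raises_lenient_keeps_most_severe(self, tmp_path):
        path = tmp_path / "in.csv"
        write_lines(path, [
            "patient_id,crs,numb",
            "P1,Baseline,Slightly",
            "P1,Baseline,Extremely",
        ])
        with pytest.raises(DuplicateRecordError, match="line 3"):
            read_custom_table(path, make_mapping(), "No Response")
        with pytest.warns(UserWarning, match="most severe"):
            t = read_custom_table(path, make_mapping(), "No Response", strict=False)
        assert t.observations[0].level == "Extremely"

    def test_reading_is_row_order_insensitive(self, tmp_path):
        rows = [
            "P1,Baseline,Not at all",
            "P1,6 mo,Slightly",
            "P2,Baseline,Moderately",
            "P2,12 mo,Extremely",
        ]
        a, b = tmp_path / "a.csv", tmp_path / "b.csv"
        write_lines(a, ["patient_id,crs,numb"] + rows)
        shuffled = rows[:]
        random.Random(7).shuffle(shuffled)
        write_lines(b, ["patient_id,crs,numb"] + shuffled)
        m = make_mapping()
        assert read_custom_table(a, m, "No Response") == read_custom_table(b, m, "No Response")

    def test_tab_delimiter(self, tmp_path):
        path = tmp_path / "in.tsv"
        write_lines(path, ["patient_id\tcrs\tnumb", "P1\tBaseline\tSlightly"])
        t = read_custom_table(path, make_mapping(), "No Response", delimiter="\t")
        assert len(t) == 1


class TestWriteCustomTable:
    def test_round_trip_identity_of_synthetic_table(self, tmp_path):
        t = simulate_trial(preset("b30-pro"), n_per_arm=20, term="numb", seed=11)
        path = tmp_path / "out.csv"
        mapping = write_custom_table(t, path)
        t2 = read_custom_table(path, mapping, t.scale.missing_level, scale=t.scale)
        assert t2 == t

    def test_empty_table_writes_header_only(self, tmp_path, ae_scale):
        from toxflow import ObservationTable

        t = ObservationTable(ae_scale, ("6 mo", "12 mo"))
        path = tmp_path / "empty.csv"
        write_custom_table(t, path)
        lines = path.read_text().strip().splitlines()
        assert len(lines) == 1 and "patient_id" in lines[0]

    def test_adversarial_labels_round_trip(self, tmp_path):
        from toxflow import Observation, ObservationTable, SeverityScale

        scale = SeverityScale(
            name="odd",
            levels=('mild, "ish"', "worse,\nmuch"),
            missing_level="gone, away",
        )
        stages = ("t0, start", 't1 "end"')
        obs = (
            Observation("P,1", "arm A", "pain, joint", "t0, start", 'mild, "ish"'),
            Observation("P,1", "arm A", "pain, joint", 't1 "end"', "worse,\nmuch"),
        )
        t = ObservationTable(scale, stages, obs)
        path = tmp_path / "weird.csv"
        mapping = write_custom_table(t, path)
        assert read_custom_table(path, mapping, scale.missing_level, scale=scale) == t

    def test_multi_term_table_rejected(self, tiny_table, tmp_path):
        with pytest.raises(SchemaError, match="one term"):
            write_custom_table(tiny_table, tmp_path / "x.csv")

    @settings(max_examples=20, derandomize=True, deadline=None)
    @given(seed=st.integers(min_value=0, max_value=10**6), n=st.integers(min_value=1, max_value=15))
    def test_round_trip_identity_property(self, tmp_path_factory, seed, n):
        t = simulate_trial(preset("b35-ae"), n_per_arm=n, term="arthralgia", seed=seed)
        path = tmp_path_factory.mktemp("rt") / "t.csv"
        mapping = write_custom_table(t, path)
        assert read_custom_table(path, mapping, t.scale.missing_level, scale=t.scale) == t

    def test_canonical_mapping_matches_table_vocabulary(self, tmp_path):
        t = simulate_trial(preset("b35-pro"), n_per_arm=5, term="hot flashes", seed=1)
        m = canonical_mapping(t)
        assert m.response_column == "hot flashes"
        assert m.time_order == t.stage_order
        assert m.response_order == bcpt_scale().levels
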