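"""Rotation, passthrough, value encoding and instance numbering."""

from __future__ import annotations

import datetime as dt
import sqlite3

import pytest
from hypothesis import given, settings, strategies as st

from txstar.eav import (
    EncodingError,
    InstanceMode,
    MalformedRowError,
    ObservationFact,
    PreEavRow,
    assign_instance_nums,
    encode_value,
    make_fact,
    passthrough,
    rotate_row,
)
from txstar.schema import ColumnMeta, ForeignKey, Role, SourceSchema, TableMeta, classify_table

DATE = dt.date(2012, 3, 4)


def _wide_table(n_values: int, n_meta_extra: int) -> TableMeta:
    """A wide table with the mandatory columns plus value/metadata columns."""
    cols = [
        ColumnMeta("row_id", Role.KEY),
        ColumnMeta("patient_id", Role.PATIENT_REF),
        ColumnMeta("event_date", Role.DATE),
    ]
    cols += [ColumnMeta(f"m{i}", Role.METADATA) for i in range(n_meta_extra)]
    cols += [ColumnMeta(f"v{i}", Role.VALUE) for i in range(n_values)]
    return TableMeta(name="Wide", columns=cols, primary_key=["row_id"])


def _schema_with(table: TableMeta) -> SourceSchema:
    patient = TableMeta("P", [ColumnMeta("pid", Role.KEY)], primary_key=["pid"])
    anchor = TableMeta(
        "Tx",
        [ColumnMeta("tid", Role.KEY), ColumnMeta("pid", Role.PATIENT_REF),
         ColumnMeta("d", Role.DATE)],
        primary_key=["tid"],
        foreign_keys=[ForeignKey("pid", "P", "pid")],
    )
    return SourceSchema(tables={"P": patient, "Tx": anchor, table.name: table},
                        anchor_table="Tx", patient_table="P")


class TestRotation:
    @given(
        n_values=st.integers(min_value=0, max_value=8),
        n_meta=st.integers(min_value=0, max_value=4),
        null_mask=st.lists(st.booleans(), min_size=8, max_size=8),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_rotation_law(self, n_values, n_meta, null_mask):
        """Emitted line count equals the non-null value cells and is bounded
        by x - y, with equality exactly when no value cell is null."""
        meta = _wide_table(n_values, n_meta)
        schema = _schema_with(meta)
        tclass = classify_table(schema, "Wide")
        row = {"row_id": 1, "patient_id": 5, "event_date": DATE.isoformat(),
               "_patient": 5, "_encounter": 77}
        for i in range(n_meta):
            row[f"m{i}"] = "meta"
        non_null = 0
        for i in range(n_values):
            if null_mask[i]:
                row[f"v{i}"] = None
            else:
                row[f"v{i}"] = f"val{i}"
                non_null += 1
        out = rotate_row(row, meta, tclass, "SRC")
        x_minus_y = meta.n_columns - meta.n_metadata
        assert len(out) == non_null
        assert len(out) <= x_minus_y
        if non_null == n_values:
            assert len(out) == x_minus_y
        assert len({r.source_event_key for r in out}) <= 1

    def test_all_metadata_row_emits_nothing(self):
        meta = _wide_table(0, 3)
        tclass = classify_table(_schema_with(meta), "Wide")
        row = {"row_id": 1, "patient_id": 2, "event_date": DATE.isoformat(),
               "_patient": 2, "_encounter": 1, "m0": "a", "m1": "b", "m2": "c"}
        assert rotate_row(row, meta, tclass, "SRC") == []

    def test_missing_patient_or_date_is_malformed(self):
        meta = _wide_table(1, 0)
        tclass = classify_table(_schema_with(meta), "Wide")
        row = {"row_id": 1, "patient_id": None, "event_date": DATE.isoformat(),
               "_patient": None, "_encounter": 1, "v0": "x"}
        with pytest.raises(MalformedRowError):
            rotate_row(row, meta, tclass, "SRC")

    def test_categorical_value_lands_in_concept_code(self):
        meta = TableMeta(
            "Diag",
            [ColumnMeta("id", Role.KEY), ColumnMeta("patient_id", Role.PATIENT_REF),
             ColumnMeta("d", Role.DATE),
             ColumnMeta("code", Role.VALUE, categorical=True)],
            primary_key=["id"],
        )
        tclass = classify_table(_schema_with(meta), "Diag")
        row = {"id": 9, "patient_id": 1, "d": DATE.isoformat(), "code": "CKD3",
               "_patient": 1, "_encounter": 4}
        (pre,) = rotate_row(row, meta, tclass, "SRC")
        assert pre.concept_code == "SRC:Diag:code:CKD3"
        assert pre.raw_value == "CKD3"


class TestPassthrough:
    @pytest.fixture()
    def lab_meta(self):
        return TableMeta(
            "Lab",
            [ColumnMeta("lab_id", Role.KEY), ColumnMeta("patient_id", Role.PATIENT_REF),
             ColumnMeta("test_id", Role.EVENT_KEY), ColumnMeta("lab_date", Role.DATE),
             ColumnMeta("analyte", Role.CONCEPT),
             ColumnMeta("value", Role.VALUE, numeric=True),
             ColumnMeta("unit", Role.UNIT, unit_of="value")],
            primary_key=["lab_id"],
        )

    def test_one_event_shares_source_event_key(self, lab_meta):
        rows = [
            {"lab_id": i, "patient_id": 3, "test_id": 500, "lab_date": DATE.isoformat(),
             "analyte": code, "value": v, "unit": "mg/dl", "_patient": 3, "_encounter": 8}
            for i, (code, v) in enumerate([("CREA", 1.1), ("UREA", 30.0), ("HB", 12.0)])
        ]
        out = passthrough(rows, lab_meta, "SRC")
        assert len(out) == 3
        assert len({r.source_event_key for r in out}) == 1
        assert {r.concept_code for r in out} == {
            "SRC:Lab:CREA", "SRC:Lab:UREA", "SRC:Lab:HB"}

    def test_bijective_on_rows(self, lab_meta):
        rows = [
            {"lab_id": i, "patient_id": 1, "test_id": i // 3, "lab_date": DATE.isoformat(),
             "analyte": "CREA", "value": float(i), "unit": "mg/dl",
             "_patient": 1, "_encounter": 2}
            for i in range(950)
        ]
        out = passthrough(rows, lab_meta, "SRC")
        assert len(out) == 950
        assert [r.raw_value for r in out] == [float(i) for i in range(950)]

    def test_empty_stream(self, lab_meta):
        assert passthrough([], lab_meta, "SRC") == []

    def test_missing_concept_value_is_malformed(self, lab_meta):
        row = {"lab_id": 1, "patient_id": 1, "test_id": 1, "lab_date": DATE.isoformat(),
               "analyte": None, "value": 1.0, "unit": "x", "_patient": 1, "_encounter": 1}
        with pytest.raises(MalformedRowError):
            passthrough([row], lab_meta, "SRC")


class TestEncoding:
    def _pre(self, value, **kw):
        return PreEavRow(patient_id=1, encounter_id=2, date=DATE, concept_code="SRC:T:c",
                         raw_value=value, source_event_key="T:1", source_table="T", **kw)

    def test_numeric_with_unit(self):
        fields = encode_value(self._pre("5.4", unit="mg/dl", numeric=True))
        assert fields == {"valtype_cd": "N", "tval_char": "E", "nval_num": 5.4,
                          "units_cd": "mg/dl", "observation_blob": None}

    def test_nonnumeric_text(self):
        fields = encode_value(self._pre("positive"))
        assert fields["valtype_cd"] == "T" and fields["tval_char"] == "positive"
        assert fields["nval_num"] is None

    def test_long_finding_goes_to_blob(self):
        text = "pathology finding " * 120  # ~2000 characters
        fields = encode_value(self._pre(text, is_blob=True))
        assert fields["valtype_cd"] == "B"
        assert fields["observation_blob"] == text
        assert fields["tval_char"] is None

    def test_declared_numeric_unparseable_raises(self):
        with pytest.raises(EncodingError):
            encode_value(self._pre("n/a", numeric=True))

    def test_fact_invariants(self):
        f = make_fact(self._pre("5.4", unit="mg/dl", numeric=True))
        assert f.valtype_cd == "N" and f.nval_num == 5.4 and f.tval_char == "E"
        g = make_fact(self._pre("hello"))
        assert g.valtype_cd == "T" and g.nval_num is None and g.units_cd is None


class TestInstanceNums:
    def _facts(self):
        def fact(pid, enc, concept, key, d=DATE):
            return make_fact(PreEavRow(
                patient_id=pid, encounter_id=enc, date=d, concept_code=concept,
                raw_value="1.0", numeric=True, source_event_key=key, source_table="Lab"))
        return [
            fact(1, 10, "SRC:Lab:CREA", "Lab:500"),
            fact(1, 10, "SRC:Lab:UREA", "Lab:500"),
            fact(1, 10, "SRC:Lab:HB", "Lab:500"),
            fact(1, 10, "SRC:Lab:CREA", "Lab:501", DATE + dt.timedelta(days=3)),
            fact(2, 11, "SRC:Lab:CREA", "Lab:502"),
        ]

    def test_grouped_shares_instance_within_event(self):
        out = assign_instance_nums(self._facts(), InstanceMode.GROUPED)
        nums = {f.source_event_key: set() for f in out}
        for f in out:
            nums[f.source_event_key].add(f.instance_num)
        assert nums["Lab:500"] == {1}
        assert nums["Lab:501"] == {2}   # later event, same patient+encounter
        assert nums["Lab:502"] == {1}   # numbering restarts per patient+encounter

    def test_idrt_compat_never_shares(self):
        out = assign_instance_nums(self._facts(), InstanceMode.IDRT_COMPAT)
        assert sorted(f.instance_num for f in out) == [1, 2, 3, 4, 5]

    def test_single_fact_gets_positive_instance(self):
        single = self._facts()[:1]
        for mode in InstanceMode:
            (f,) = assign_instance_nums(single, mode)
            assert f.instance_num >= 1

    def test_sql_stamping_matches_in_memory_route(self, tmp_path):
        """The loader's SQL window-function stamping agrees with the
        in-memory grouping for both modes."""
        from txstar.ontology import ConceptRecord, build_ontology
        from txstar.star import load

        facts = self._facts()
        concepts = build_ontology(
            [ConceptRecord("Lab", None, c, f"SRC:Lab:{c}") for c in ("CREA", "UREA", "HB")]
        )
        patients = [{"patient_num": 1}, {"patient_num": 2}]
        for mode in InstanceMode:
            expected = {
                (f.patient_num, f.encounter_num, f.concept_cd, f.source_event_key):
                    f.instance_num
                for f in assign_instance_nums(facts, mode)
            }
            db = load(list(facts), patients, concepts,
                      tmp_path / f"star_{mode.value}.db", instance_mode=mode)
            got = {
                (p, e, c, k): n
                for p, e, c, k, n in db.conn.execute(
                    "SELECT patient_num, encounter_num, concept_cd, source_event_key,"
                    " instance_num FROM observation_fact")
            }
            db.close()
            assert got == expected
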