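"""Source-schema loading, FK traversal and five-type classification."""

from __future__ import annotations

import random

import networkx as nx
import pytest

from txstar.schema import (
    ColumnMeta,
    ConfigError,
    DataFlag,
    ForeignKey,
    Role,
    SchemaError,
    SourceSchema,
    StructureType,
    TableMeta,
    UnclassifiableTableError,
    classify_table,
    fk_path,
    load_schema,
)


def _cols(*specs):
    return [ColumnMeta(name=n, role=r) for n, r in specs]


def _table(name, cols, pk=None, fks=()):
    return TableMeta(name=name, columns=cols, primary_key=pk or [cols[0].name],
                     foreign_keys=list(fks))


@pytest.fixture()
def chain_schema() -> SourceSchema:
    """Patient <- Transplantation <- Diagnosis <- Medication, plus Examination."""
    tables = {
        "Patient": _table("Patient", _cols(("patient_id", Role.KEY))),
        "Transplantation": _table(
            "Transplantation",
            _cols(("transplant_id", Role.KEY), ("patient_id", Role.PATIENT_REF),
                  ("transplant_date", Role.DATE)) + [
                ColumnMeta(name="organ", role=Role.VALUE, categorical=True)],
            fks=[ForeignKey("patient_id", "Patient", "patient_id")],
        ),
        "Diagnosis": _table(
            "Diagnosis",
            _cols(("diag_id", Role.KEY), ("transplant_id", Role.KEY),
                  ("diag_date", Role.DATE)) + [
                ColumnMeta(name="diag_code", role=Role.VALUE, categorical=True)],
            fks=[ForeignKey("transplant_id", "Transplantation", "transplant_id")],
        ),
        "Medication": _table(
            "Medication",
            _cols(("med_id", Role.KEY), ("diag_id", Role.KEY), ("start_date", Role.DATE)) + [
                ColumnMeta(name="drug", role=Role.VALUE, categorical=True)],
            fks=[ForeignKey("diag_id", "Diagnosis", "diag_id")],
        ),
        "Examination": _table(
            "Examination",
            _cols(("exam_id", Role.KEY), ("patient_id", Role.PATIENT_REF),
                  ("exam_date", Role.DATE), ("result", Role.VALUE)),
        ),
        "Donor": _table("Donor", _cols(("donor_id", Role.KEY))),
    }
    return SourceSchema(tables=tables, anchor_table="Transplantation", patient_table="Patient")


class TestLoadSchema:
    def test_fig1_like_config_resolves_anchor(self):
        cfg = {
            "anchor_table": "Transplantation",
            "patient_table": "Patient",
            "tables": {
                "Patient": {"primary_key": ["pid"], "columns": [{"name": "pid", "role": "KEY"}]},
                "Transplantation": {
                    "primary_key": ["tid"],
                    "columns": [
                        {"name": "tid", "role": "KEY"},
                        {"name": "pid", "role": "PATIENT_REF"},
                        {"name": "tx_date", "role": "DATE"},
                    ],
                    "foreign_keys": [{"column": "pid", "references": "Patient.pid"}],
                },
                "Diagnosis": {
                    "primary_key": ["did"],
                    "columns": [
                        {"name": "did", "role": "KEY"},
                        {"name": "tid", "role": "KEY"},
                        {"name": "d_date", "role": "DATE"},
                        {"name": "code", "role": "VALUE"},
                    ],
                    "foreign_keys": [{"column": "tid", "references": "Transplantation.tid"}],
                },
            },
        }
        schema = load_schema(cfg)
        assert schema.anchor_table == "Transplantation"
        assert fk_path(schema, "Diagnosis") is not None

    def test_empty_table_list_is_config_error(self):
        with pytest.raises(ConfigError):
            load_schema({"anchor_table": "A", "patient_table": "P", "tables": {}})

    def test_fk_to_nonexistent_table_names_offender(self):
        cfg = {
            "anchor_table": "T",
            "patient_table": "P",
            "tables": {
                "P": {"primary_key": ["p"], "columns": [{"name": "p", "role": "KEY"}]},
                "T": {
                    "primary_key": ["t"],
                    "columns": [{"name": "t"}, {"name": "p"}, {"name": "d2"}],
                    "foreign_keys": [
                        {"column": "p", "references": "P.p"},
                        {"column": "d2", "references": "Donor2.id"},
                    ],
                },
            },
        }
        with pytest.raises(SchemaError, match="Donor2"):
            load_schema(cfg)

    def test_missing_anchor_is_config_error(self):
        with pytest.raises(ConfigError):
            load_schema({
                "anchor_table": "Nope", "patient_table": "P",
                "tables": {"P": {"primary_key": ["p"], "columns": [{"name": "p"}]}},
            })


class TestFkPath:
    @pytest.mark.parametrize(
        "table,length",
        [("Diagnosis", 1), ("Medication", 2), ("Transplantation", 0)],
    )
    def test_path_lengths(self, chain_schema, table, length):
        path = fk_path(chain_schema, table)
        assert path is not None and len(path) == length

    def test_no_path_is_absent_not_error(self, chain_schema):
        assert fk_path(chain_schema, "Examination") is None
        assert fk_path(chain_schema, "Donor") is None

    def test_agrees_with_networkx_on_random_graphs(self):
        """BFS shortest path matches an independent graph library on random
        FK graphs of up to 12 tables, including cyclic ones."""
        rng = random.Random(20240811)
        for trial in range(60):
            n = rng.randint(2, 12)
            names = [f"T{i}" for i in range(n)]
            g = nx.DiGraph()
            g.add_nodes_from(names)
            tables = {}
            fks = {name: [] for name in names}
            for src in names:
                for dst in rng.sample(names, k=rng.randint(0, min(3, n - 1))):
                    if dst != src and not any(f.ref_table == dst for f in fks[src]):
                        fks[src].append(ForeignKey(f"fk_{dst}", dst, "id"))
                        g.add_edge(src, dst)
            anchor = "T0"
            # anchor needs a patient FK for schema validity
            if not any(f.ref_table == "T1" for f in fks[anchor]) and n > 1:
                fks[anchor].append(ForeignKey("fk_patient", "T1", "id"))
                g.add_edge(anchor, "T1")
            for name in names:
                cols = [ColumnMeta(name="id", role=Role.KEY)] + [
                    ColumnMeta(name=f.column, role=Role.KEY) for f in fks[name]
                ]
                tables[name] = TableMeta(name=name, columns=cols, primary_key=["id"],
                                         foreign_keys=fks[name])
            schema = SourceSchema(tables=tables, anchor_table=anchor,
                                  patient_table="T1" if n > 1 else "T0")
            for table in names:
                path = fk_path(schema, table, anchor)
                try:
                    expected = nx.shortest_path_length(g, table, anchor)
                except nx.NetworkXNoPath:
                    expected = None
                if expected is None:
                    assert path is None
                else:
                    assert path is not None and len(path) == expected


class TestClassification:
    def test_lab_table_is_eav_ready_and_unit_bearing(self):
        lab = TableMeta(
            name="Lab",
            columns=[
                ColumnMeta("lab_id", Role.KEY),
                ColumnMeta("patient_ref", Role.PATIENT_REF),
                ColumnMeta("date", Role.DATE),
                ColumnMeta("analyte_code", Role.CONCEPT),
                ColumnMeta("value", Role.VALUE, numeric=True),
                ColumnMeta("unit", Role.UNIT, unit_of="value"),
            ],
            primary_key=["lab_id"],
        )
        patient = TableMeta(name="P", columns=[ColumnMeta("pid", Role.KEY)], primary_key=["pid"])
        anchor = TableMeta(
            name="Tx",
            columns=[ColumnMeta("tid", Role.KEY), ColumnMeta("pid", Role.PATIENT_REF),
                     ColumnMeta("d", Role.DATE)],
            primary_key=["tid"],
            foreign_keys=[ForeignKey("pid", "P", "pid")],
        )
        schema = SourceSchema(tables={"P": patient, "Tx": anchor, "Lab": lab},
                              anchor_table="Tx", patient_table="P")
        c = classify_table(schema, "Lab")
        assert c.structure_type is StructureType.EAV_READY
        assert c.data_flags == frozenset({DataFlag.UNIT_BEARING})

    def test_finding_table_is_anchor_linked_blob(self, chain_schema):
        chain_schema.tables["Finding"] = TableMeta(
            name="Finding",
            columns=[ColumnMeta("fid", Role.KEY), ColumnMeta("transplant_id", Role.KEY),
                     ColumnMeta("f_date", Role.DATE), ColumnMeta("text", Role.FREE_TEXT)],
            primary_key=["fid"],
            foreign_keys=[ForeignKey("transplant_id", "Transplantation", "transplant_id")],
        )
        c = classify_table(chain_schema, "Finding")
        assert c.structure_type is StructureType.ANCHOR_LINKED
        assert c.data_flags == frozenset({DataFlag.FREE_TEXT_BLOB})

    def test_examination_is_unlinked(self, chain_schema):
        c = classify_table(chain_schema, "Examination")
        assert c.structure_type is StructureType.UNLINKED
        assert c.fk_path is None

    def test_anchor_itself_is_linked_with_identity_path(self, chain_schema):
        c = classify_table(chain_schema, "Transplantation")
        assert c.structure_type is StructureType.ANCHOR_LINKED
        assert c.fk_path == ()

    def test_donor_is_unclassifiable(self, chain_schema):
        with pytest.raises(UnclassifiableTableError):
            classify_table(chain_schema, "Donor")

    def test_classification_total_and_deterministic(self, chain_schema):
        classifiable = [t for t in chain_schema.tables if t not in ("Donor", "Patient")]
        first = {t: classify_table(chain_schema, t) for t in classifiable}
        second = {t: classify_table(chain_schema, t) for t in reversed(classifiable)}
        assert first == second
        assert all(v.structure_type is not None for v in first.values())
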