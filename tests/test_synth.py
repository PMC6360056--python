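"""Generator contracts: determinism, integrity, truth recounts, scaling."""

from __future__ import annotations

import hashlib
import sqlite3

import pytest

from txstar import oracle
from txstar.synth import (
    GeneratorConfig,
    REFERENCE_COUNTS,
    SOURCE_TABLES,
    generate,
    scale_profile,
)


def _content_hash(db_path) -> str:
    conn = sqlite3.connect(str(db_path))
    h = hashlib.sha256()
    for table in SOURCE_TABLES:
        for row in conn.execute(f'SELECT * FROM "{table}" ORDER BY rowid'):
            h.update(repr(row).encode())
    conn.close()
    return h.hexdigest()


class TestDeterminism:
    def test_same_seed_same_content(self, tmp_path):
        cfg = GeneratorConfig(seed=11, n_patients=40, tests_per_patient_mean=10,
                              planted_cohorts={1: 2, 2: 2, 3: 2, 4: 2})
        a, _ = generate(cfg, tmp_path / "a.db")
        b, _ = generate(cfg, tmp_path / "b.db")
        assert _content_hash(a) == _content_hash(b)

    def test_different_seed_different_content(self, tmp_path):
        a, _ = generate(GeneratorConfig(seed=1, n_patients=30, tests_per_patient_mean=5, planted_cohorts={}),
                        tmp_path / "a.db")
        b, _ = generate(GeneratorConfig(seed=2, n_patients=30, tests_per_patient_mean=5, planted_cohorts={}),
                        tmp_path / "b.db")
        assert _content_hash(a) != _content_hash(b)


class TestIntegrity:
    def test_referential_integrity(self, source_conn):
        checks = [
            ("Transplantation", "patient_id", "Patient", "patient_id"),
            ("Transplantation", "donor_id", "Donor", "donor_id"),
            ("LabValue", "patient_id", "Patient", "patient_id"),
            ("Diagnosis", "transplant_id", "Transplantation", "transplant_id"),
            ("Examination", "patient_id", "Patient", "patient_id"),
            ("Finding", "transplant_id", "Transplantation", "transplant_id"),
            ("Medication", "transplant_id", "Transplantation", "transplant_id"),
        ]
        for table, col, ref, refcol in checks:
            dangling = source_conn.execute(
                f'SELECT COUNT(*) FROM "{table}" t LEFT JOIN "{ref}" r'
                f' ON t."{col}" = r."{refcol}" WHERE r."{refcol}" IS NULL'
            ).fetchone()[0]
            assert dangling == 0, (table, col)

    def test_temporal_sanity(self, source_conn):
        bad = source_conn.execute(
            "SELECT COUNT(*) FROM Transplantation"
            " WHERE failure_date IS NOT NULL AND failure_date < transplant_date"
        ).fetchone()[0]
        assert bad == 0
        # per-patient transplants strictly ordered in time
        dup = source_conn.execute(
            "SELECT patient_id, transplant_date, COUNT(*) AS n FROM Transplantation"
            " GROUP BY patient_id, transplant_date HAVING n > 1"
        ).fetchall()
        assert dup == []

    def test_truth_counts_match_recount(self, source, source_conn):
        _, truth = source
        recount = {
            "Transplantation": "SELECT COUNT(organ) FROM Transplantation",
            "LabValue": "SELECT COUNT(value_num) FROM LabValue",
            "Diagnosis": "SELECT COUNT(diag_code) FROM Diagnosis",
            "Examination": "SELECT COUNT(exam_type) + COUNT(result_num) FROM Examination",
            "Finding": "SELECT COUNT(finding_text) FROM Finding",
            "Medication": "SELECT COUNT(drug_code) FROM Medication",
        }
        for table, sql in recount.items():
            assert truth.per_entity_row_counts[table] == source_conn.execute(sql).fetchone()[0]

    def test_planted_truth_is_oracle_answer_and_covers_request(self, source, source_conn,
                                                               default_config):
        _, truth = source
        for sid, requested in default_config.planted_cohorts.items():
            answer = oracle.eval_study_on_source(source_conn, sid)
            assert set(truth.per_study_patients[sid]) == answer
            assert len(answer) >= requested

    def test_some_examinations_fall_outside_every_window(self, source, source_conn):
        """Surrogate-zone guarantee: examinations exist before the first
        transplantation window of their patient."""
        n = source_conn.execute(
            """
            SELECT COUNT(*) FROM Examination e
            WHERE e.exam_date < (
                SELECT DATE(MIN(t.transplant_date), '-14 day') FROM Transplantation t
                WHERE t.patient_id = e.patient_id)
            """
        ).fetchone()[0]
        assert n > 0


class TestDegenerate:
    def test_zero_patients_empty_tables(self, tmp_path):
        cfg = GeneratorConfig(n_patients=0, planted_cohorts={})
        path, truth = generate(cfg, tmp_path / "z.db")
        conn = sqlite3.connect(str(path))
        for table in SOURCE_TABLES:
            assert conn.execute(f'SELECT COUNT(*) FROM "{table}"').fetchone()[0] == 0
        assert all(v == 0 for v in truth.per_entity_row_counts.values())

    def test_planted_cohort_larger_than_population_rejected(self):
        with pytest.raises(ValueError):
            GeneratorConfig(n_patients=5, planted_cohorts={2: 7})


class TestScaleProfile:
    def test_upscale_guard(self):
        with pytest.raises(ValueError):
            scale_profile(1.5)
        assert scale_profile(1.5, allow_upscale=True).n_patients > REFERENCE_COUNTS["patients"]

    def test_tiny_factor_rounds_to_few_patients(self):
        cfg = scale_profile(1e-3)
        assert 2 <= cfg.n_patients <= 4

    def test_counts_within_three_sigma_of_expectation(self, tmp_path):
        """A generated 1% profile hits the config's own expected per-entity
        counts within 3 sigma."""
        cfg = scale_profile(0.01, seed=303)
        path, truth = generate(cfg, tmp_path / "s.db")
        conn = sqlite3.connect(str(path))
        actual = {
            t: conn.execute(f'SELECT COUNT(*) FROM "{t}"').fetchone()[0]
            for t in ("Transplantation", "LabValue", "Diagnosis", "Medication",
                      "Examination", "Finding")
        }
        for table, (mean, sd) in cfg.expected_counts().items():
            if table == "Patient":
                continue
            assert abs(actual[table] - mean) <= 3 * sd + 1, (table, actual[table], mean, sd)

    def test_expected_scale_tracks_reference(self):
        cfg = scale_profile(0.01)
        expected = cfg.expected_counts()
        assert cfg.n_patients == 35
        assert abs(expected["LabValue"][0] - REFERENCE_COUNTS["lab_values"] * 0.01) < 2500
        assert abs(expected["Transplantation"][0] - REFERENCE_COUNTS["transplants"] * 0.01) < 2
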