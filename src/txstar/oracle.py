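"""Independent SQL evaluation of the bundled studies on the relational source.

Each bundled cohort question is answered here directly on the *source*
database with plain SQL over the original relational tables — no EAV, no
star schema, no shared code with the query engine. This is the reference
route: the mapping is considered answer-preserving exactly when the star-side
query engine returns the same patient set.

The numeric thresholds, dates and gap lengths live in ``STUDY_PARAMS`` and
are shared with the bundled study definitions so both routes ask the same
question.
"""

from __future__ import annotations

import sqlite3
from typing import Set

__all__ = ["STUDY_PARAMS", "eval_study_on_source"]

#: Parameters of the four bundled cohort questions.
STUDY_PARAMS = {
    1: {
        "analytes": ("CREA", "UREA", "HB"),
        "crea_threshold": 1.5,
    },
    2: {
        "hcv_analyte": "HCV",
        "hcv_threshold": 0.0,
        "death_code": "DEATH",
        "followup_type": "FOLLOWUP",
    },
    3: {
        "organ": "KIDNEY",
        "excluded_organ": "PANCREAS",
        "window_start": "2004-01-01",
        "rejection_code": "REJ",
        "keyword_pattern": "%urin%tract%",
    },
    4: {
        "ckd_code": "CKD3",
        "transplant_after": "2003-01-01",
        "gap_days": 183,
        "hb_analyte": "HB",
        "hb_low": 10.0,
        "hb_high": 14.0,
        "uacr_analyte": "UACR",
        "uacr_max": 30.0,
        "esa_code": "ESA",
        "esa_window_days": 183,
    },
}


def _patients(conn: sqlite3.Connection, sql: str, params: tuple = ()) -> Set[int]:
    return {row[0] for row in conn.execute(sql, params)}


def _study1(conn: sqlite3.Connection) -> Set[int]:
    p = STUDY_PARAMS[1]
    a1, a2, a3 = p["analytes"]
    triple = _patients(
        conn,
        """
        SELECT DISTINCT l1.patient_id
        FROM LabValue l1
        JOIN LabValue l2 ON l2.patient_id = l1.patient_id AND l2.test_id = l1.test_id
        JOIN LabValue l3 ON l3.patient_id = l1.patient_id AND l3.test_id = l1.test_id
        WHERE l1.analyte_code = ? AND l2.analyte_code = ? AND l3.analyte_code = ?
        """,
        (a1, a2, a3),
    )
    elevated = _patients(
        conn,
        "SELECT DISTINCT patient_id FROM LabValue WHERE analyte_code = ? AND value_num > ?",
        (a1, p["crea_threshold"]),
    )
    after_tx = _patients(
        conn,
        """
        SELECT DISTINCT l.patient_id FROM LabValue l
        JOIN Transplantation t ON t.patient_id = l.patient_id
        WHERE l.analyte_code = ? AND l.lab_date > t.transplant_date
        """,
        (STUDY_PARAMS[1]["analytes"][0],),
    )
    return triple & elevated & after_tx


def _study2(conn: sqlite3.Connection) -> Set[int]:
    p = STUDY_PARAMS[2]
    positive = _patients(
        conn,
        "SELECT DISTINCT patient_id FROM LabValue WHERE analyte_code = ? AND value_num > ?",
        (p["hcv_analyte"], p["hcv_threshold"]),
    )
    dead = _patients(
        conn,
        """
        SELECT DISTINCT t.patient_id FROM Diagnosis d
        JOIN Transplantation t ON t.transplant_id = d.transplant_id
        WHERE d.diag_code = ?
        """,
        (p["death_code"],),
    )
    alive = _patients(conn, "SELECT patient_id FROM Patient") - dead
    followup = _patients(
        conn,
        """
        SELECT DISTINCT e.patient_id FROM Examination e
        JOIN Transplantation t ON t.patient_id = e.patient_id
        WHERE e.exam_type = ? AND e.exam_date > t.transplant_date
        """,
        (p["followup_type"],),
    )
    return positive & alive & followup


def _study3(conn: sqlite3.Connection) -> Set[int]:
    p = STUDY_PARAMS[3]
    kidney = _patients(
        conn, "SELECT DISTINCT patient_id FROM Transplantation WHERE organ = ?", (p["organ"],)
    )
    pancreas = _patients(
        conn,
        "SELECT DISTINCT patient_id FROM Transplantation WHERE organ = ?",
        (p["excluded_organ"],),
    )
    in_window = _patients(
        conn,
        "SELECT DISTINCT patient_id FROM Transplantation WHERE transplant_date >= ?",
        (p["window_start"],),
    )
    uti_between = _patients(
        conn,
        """
        SELECT DISTINCT t.patient_id
        FROM Transplantation t
        JOIN Finding f ON f.transplant_id IN (
            SELECT t2.transplant_id FROM Transplantation t2 WHERE t2.patient_id = t.patient_id
        )
        JOIN Diagnosis r ON r.transplant_id IN (
            SELECT t3.transplant_id FROM Transplantation t3 WHERE t3.patient_id = t.patient_id
        )
        WHERE LOWER(f.finding_text) LIKE ?
          AND r.diag_code = ?
          AND f.finding_date > t.transplant_date
          AND f.finding_date < r.diag_date
        """,
        (p["keyword_pattern"].lower(), p["rejection_code"]),
    )
    return (kidney & in_window & uti_between) - pancreas


def _study4(conn: sqlite3.Connection) -> Set[int]:
    p = STUDY_PARAMS[4]
    ckd = _patients(
        conn,
        """
        SELECT DISTINCT t.patient_id FROM Diagnosis d
        JOIN Transplantation t ON t.transplant_id = d.transplant_id
        WHERE d.diag_code = ?
        """,
        (p["ckd_code"],),
    )
    tx_after = _patients(
        conn,
        "SELECT DISTINCT patient_id FROM Transplantation WHERE transplant_date >= ?",
        (p["transplant_after"],),
    )

    def most_recent_ok(analyte: str, low, high) -> Set[int]:
        # candidates: labs >= gap_days after *some* transplantation; the
        # check applies to any value on the latest candidate date.
        rows = conn.execute(
            """
            WITH candidates AS (
                SELECT l.patient_id, l.lab_date, l.value_num
                FROM LabValue l
                WHERE l.analyte_code = :analyte
                  AND EXISTS (
                    SELECT 1 FROM Transplantation t
                    WHERE t.patient_id = l.patient_id
                      AND julianday(l.lab_date) - julianday(t.transplant_date) >= :gap
                  )
            ),
            latest AS (
                SELECT patient_id, MAX(lab_date) AS d FROM candidates GROUP BY patient_id
            )
            SELECT c.patient_id, c.value_num
            FROM candidates c JOIN latest m
              ON m.patient_id = c.patient_id AND m.d = c.lab_date
            """,
            {"analyte": analyte, "gap": p["gap_days"]},
        )
        lo_ok, hi_ok = set(), set()
        for pid, v in rows:
            if low is None or v >= low:
                lo_ok.add(pid)
            if high is None or v <= high:
                hi_ok.add(pid)
        return lo_ok & hi_ok

    hb_ok = most_recent_ok(p["hb_analyte"], p["hb_low"], p["hb_high"])
    uacr_ok = most_recent_ok(p["uacr_analyte"], None, p["uacr_max"])

    esa_early = _patients(
        conn,
        """
        SELECT DISTINCT t.patient_id
        FROM Medication m
        JOIN Transplantation mt ON mt.transplant_id = m.transplant_id
        JOIN Transplantation t ON t.patient_id = mt.patient_id
        WHERE m.drug_code = ?
          AND julianday(m.start_date) - julianday(t.transplant_date) >= 0
          AND julianday(m.start_date) - julianday(t.transplant_date) <= ?
        """,
        (p["esa_code"], p["esa_window_days"]),
    )
    return (ckd & tx_after & hb_ok & uacr_ok) - esa_early


_STUDIES = {1: _study1, 2: _study2, 3: _study3, 4: _study4}


def eval_study_on_source(conn: sqlite3.Connection, study_id: int) -> Set[int]:
    """Patient set satisfying bundled study ``study_id`` on the source DB."""
    try:
        fn = _STUDIES[study_id]
    except KeyError:
        raise KeyError(f"unknown bundled study id {study_id}") from None
    return fn(conn)
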