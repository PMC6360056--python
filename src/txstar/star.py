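"""Materialize and verify the i2b2 star schema.

Only the fact table, the patient dimension and the metadata (ontology) table
are written from transformed data; the visit, concept, provider and modifier
dimensions are derived by SQL from what is already loaded — deriving the
secondary tables is cheaper than exporting them and cannot drift from the
facts. Every load is stamped with an ``upload_id`` and re-loading the same
id first deletes that run's rows, so the loader is safely re-entrant.

``verify_counts`` reproduces the end-of-load verification: for every source
table, the number of non-null value cells in the source must equal the
number of facts loaded from it; any inequality is itemized, never raised.
"""

from __future__ import annotations

import csv
import logging
import sqlite3
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Optional, Sequence

from .eav import DEFAULT_MODIFIER, DEFAULT_PROVIDER, InstanceMode, ObservationFact
from .ontology import OntologyNode, derive_concept_dimension
from .schema import Role, SourceSchema, StructureType, TableClass, TableMeta

__all__ = [
    "StarDatabase",
    "VerificationReport",
    "LoadError",
    "load",
    "verify_counts",
    "count_value_cells",
    "export_csv",
]

log = logging.getLogger(__name__)

STAR_TABLES = (
    "observation_fact",
    "patient_dimension",
    "visit_dimension",
    "concept_dimension",
    "provider_dimension",
    "modifier_dimension",
    "i2b2",
)

_DDL = """
CREATE TABLE IF NOT EXISTS observation_fact (
    encounter_num INTEGER NOT NULL,
    patient_num INTEGER NOT NULL,
    concept_cd TEXT NOT NULL,
    provider_id TEXT NOT NULL DEFAULT '@',
    start_date TEXT NOT NULL,
    modifier_cd TEXT NOT NULL DEFAULT '@',
    instance_num INTEGER NOT NULL DEFAULT 1,
    valtype_cd TEXT,
    tval_char TEXT,
    nval_num REAL,
    units_cd TEXT,
    observation_blob TEXT,
    sourcesystem_cd TEXT,
    source_event_key TEXT,
    upload_id INTEGER NOT NULL DEFAULT 1
);
CREATE TABLE IF NOT EXISTS patient_dimension (
    patient_num INTEGER PRIMARY KEY,
    birth_date TEXT,
    sex_cd TEXT,
    sourcesystem_cd TEXT,
    upload_id INTEGER NOT NULL DEFAULT 1
);
CREATE TABLE IF NOT EXISTS visit_dimension (
    encounter_num INTEGER NOT NULL,
    patient_num INTEGER NOT NULL,
    start_date TEXT,
    end_date TEXT,
    upload_id INTEGER NOT NULL DEFAULT 1,
    PRIMARY KEY (encounter_num, patient_num)
);
CREATE TABLE IF NOT EXISTS concept_dimension (
    concept_path TEXT PRIMARY KEY,
    concept_cd TEXT,
    name_char TEXT,
    upload_id INTEGER NOT NULL DEFAULT 1
);
CREATE TABLE IF NOT EXISTS provider_dimension (
    provider_path TEXT PRIMARY KEY,
    provider_id TEXT,
    name_char TEXT
);
CREATE TABLE IF NOT EXISTS modifier_dimension (
    modifier_path TEXT PRIMARY KEY,
    modifier_cd TEXT,
    name_char TEXT
);
CREATE TABLE IF NOT EXISTS i2b2 (
    c_hlevel INTEGER NOT NULL,
    c_fullname TEXT NOT NULL,
    c_name TEXT NOT NULL,
    c_basecode TEXT,
    c_visualattributes TEXT NOT NULL,
    c_synonym_cd TEXT NOT NULL DEFAULT 'N',
    c_facttablecolumn TEXT NOT NULL DEFAULT 'concept_cd',
    c_tablename TEXT NOT NULL DEFAULT 'observation_fact',
    c_columnname TEXT NOT NULL DEFAULT 'concept_path',
    c_operator TEXT NOT NULL DEFAULT 'LIKE',
    upload_id INTEGER NOT NULL DEFAULT 1
);
"""

_FACT_COLS = (
    "encounter_num",
    "patient_num",
    "concept_cd",
    "provider_id",
    "start_date",
    "modifier_cd",
    "instance_num",
    "valtype_cd",
    "tval_char",
    "nval_num",
    "units_cd",
    "observation_blob",
    "sourcesystem_cd",
    "source_event_key",
    "upload_id",
)


class LoadError(RuntimeError):
    pass


@dataclass
class StarDatabase:
    """Handle on a loaded star schema (a SQLite database file)."""

    path: Path
    conn: sqlite3.Connection
    instance_mode: InstanceMode = InstanceMode.GROUPED
    upload_id: int = 1

    def fact_count(self) -> int:
        return self.conn.execute("SELECT COUNT(*) FROM observation_fact").fetchone()[0]

    def close(self) -> None:
        self.conn.close()


@dataclass
class VerificationReport:
    """Per-source-table fact-count reconciliation."""

    per_table: dict[str, tuple[int, int, bool]]
    skipped: list[str] = field(default_factory=list)

    @property
    def overall_equal(self) -> bool:
        return all(flag for _, _, flag in self.per_table.values())

    def to_dict(self) -> dict:
        return {
            "per_table": {
                t: {"source_value_cells": s, "loaded_facts": f, "equal": eq}
                for t, (s, f, eq) in sorted(self.per_table.items())
            },
            "skipped_tables": sorted(self.skipped),
            "overall_equal": self.overall_equal,
        }

    def summary(self) -> str:
        lines = ["count verification:"]
        for t, (s, f, eq) in sorted(self.per_table.items()):
            mark = "OK " if eq else "FAIL"
            lines.append(f"  [{mark}] {t}: source {s} / loaded {f}")
        if self.skipped:
            lines.append(f"  skipped: {', '.join(sorted(self.skipped))}")
        lines.append(f"  overall_equal: {self.overall_equal}")
        return "\n".join(lines)


def _open(target: Path | str) -> sqlite3.Connection:
    conn = sqlite3.connect(str(target))
    conn.executescript(_DDL)
    return conn


def load(
    facts: Iterable[ObservationFact],
    patients: Iterable[Mapping],
    ontology: "Sequence[OntologyNode] | Callable[[], Sequence[OntologyNode]]",
    target: Path | str,
    *,
    instance_mode: InstanceMode = InstanceMode.GROUPED,
    upload_id: int = 1,
    chunk_size: int = 50_000,
) -> StarDatabase:
    """Load facts, patients and the ontology into a star-schema database.

    Facts are inserted chunk-wise, instance numbers are stamped in SQL over
    the staged fact table (grouping spans source tables), derived dimensions
    are generated by SQL, and the fact-key uniqueness invariant is enforced
    at the end. Rows of a previous run with the same upload id are replaced.

    ``ontology`` may be a callable; it is invoked only after the fact stream
    is exhausted, so a caller can collect the observed concepts while
    streaming facts.
    """
    path = Path(target)
    conn = _open(path)
    with conn:
        for t in ("observation_fact", "patient_dimension", "visit_dimension", "concept_dimension"):
            conn.execute(f"DELETE FROM {t} WHERE upload_id = ?", (upload_id,))
        conn.execute("DELETE FROM i2b2 WHERE upload_id = ?", (upload_id,))

        buf: list[tuple] = []
        for fact in facts:
            buf.append(
                (
                    fact.encounter_num,
                    fact.patient_num,
                    fact.concept_cd,
                    fact.provider_id,
                    fact.start_date.isoformat(),
                    fact.modifier_cd,
                    fact.instance_num,
                    fact.valtype_cd,
                    fact.tval_char,
                    fact.nval_num,
                    fact.units_cd,
                    fact.observation_blob,
                    fact.sourcesystem_cd,
                    fact.source_event_key,
                    upload_id,
                )
            )
            if len(buf) >= chunk_size:
                _insert_facts(conn, buf)
                buf.clear()
        if buf:
            _insert_facts(conn, buf)

        conn.executemany(
            "INSERT INTO patient_dimension (patient_num, birth_date, sex_cd, sourcesystem_cd, upload_id)"
            " VALUES (?, ?, ?, ?, ?)",
            [
                (
                    int(p["patient_num"]),
                    p.get("birth_date"),
                    p.get("sex_cd"),
                    p.get("sourcesystem_cd", ""),
                    upload_id,
                )
                for p in patients
            ],
        )

        nodes = ontology() if callable(ontology) else ontology
        conn.executemany(
            "INSERT INTO i2b2 (c_hlevel, c_fullname, c_name, c_basecode, c_visualattributes,"
            " c_synonym_cd, upload_id) VALUES (?, ?, ?, ?, ?, ?, ?)",
            [
                (n.c_hlevel, n.c_fullname, n.c_name, n.c_basecode, n.c_visualattributes,
                 n.c_synonym_cd, upload_id)
                for n in nodes
            ],
        )

        _stamp_instance_nums(conn, instance_mode, upload_id)
        _derive_dimensions(conn, nodes, upload_id)
        _check_invariants(conn, upload_id)
    return StarDatabase(path=path, conn=conn, instance_mode=instance_mode, upload_id=upload_id)


def _insert_facts(conn: sqlite3.Connection, rows: list[tuple]) -> None:
    conn.executemany(
        f"INSERT INTO observation_fact ({', '.join(_FACT_COLS)}) "
        f"VALUES ({', '.join('?' * len(_FACT_COLS))})",
        rows,
    )


def _stamp_instance_nums(
    conn: sqlite3.Connection, mode: InstanceMode, upload_id: int
) -> None:
    # SQL mirror of eav.assign_instance_nums (the in-memory route); a test
    # pins the two routes to each other.
    if mode is InstanceMode.GROUPED:
        rank_sql = (
            "SELECT rowid AS rid, DENSE_RANK() OVER ("
            " PARTITION BY patient_num, encounter_num"
            " ORDER BY start_date, source_event_key) AS rk"
            " FROM observation_fact WHERE upload_id = :uid"
        )
    else:
        rank_sql = (
            "SELECT rowid AS rid, ROW_NUMBER() OVER (ORDER BY rowid) AS rk"
            " FROM observation_fact WHERE upload_id = :uid"
        )
    conn.execute(
        f"UPDATE observation_fact SET instance_num = r.rk FROM ({rank_sql}) AS r "
        "WHERE observation_fact.rowid = r.rid",
        {"uid": upload_id},
    )


def _derive_dimensions(
    conn: sqlite3.Connection, ontology: Sequence[OntologyNode], upload_id: int
) -> None:
    conn.execute(
        "INSERT INTO visit_dimension (encounter_num, patient_num, start_date, end_date, upload_id) "
        "SELECT encounter_num, patient_num, MIN(start_date), MAX(start_date), ? "
        "FROM observation_fact WHERE upload_id = ? GROUP BY encounter_num, patient_num",
        (upload_id, upload_id),
    )
    conn.executemany(
        "INSERT INTO concept_dimension (concept_path, concept_cd, name_char, upload_id) "
        "VALUES (?, ?, ?, ?)",
        [(p, c, n, upload_id) for p, c, n in derive_concept_dimension(ontology)],
    )
    conn.execute(
        "INSERT OR IGNORE INTO provider_dimension (provider_path, provider_id, name_char) "
        "VALUES (?, ?, ?)",
        ("\\@\\", DEFAULT_PROVIDER, "none"),
    )
    conn.execute(
        "INSERT OR IGNORE INTO modifier_dimension (modifier_path, modifier_cd, name_char) "
        "VALUES (?, ?, ?)",
        ("\\@\\", DEFAULT_MODIFIER, "none"),
    )


def _check_invariants(conn: sqlite3.Connection, upload_id: int) -> None:
    dup = conn.execute(
        "SELECT encounter_num, patient_num, concept_cd, provider_id, start_date,"
        " modifier_cd, instance_num, COUNT(*) AS n FROM observation_fact"
        " WHERE upload_id = ? GROUP BY 1,2,3,4,5,6,7 HAVING n > 1 LIMIT 1",
        (upload_id,),
    ).fetchone()
    if dup:
        raise LoadError(f"fact-key uniqueness violated for key {dup[:7]}")
    orphan = conn.execute(
        "SELECT f.patient_num FROM observation_fact f LEFT JOIN patient_dimension p"
        " ON f.patient_num = p.patient_num WHERE p.patient_num IS NULL"
        " AND f.upload_id = ? LIMIT 1",
        (upload_id,),
    ).fetchone()
    if orphan:
        raise LoadError(f"fact references patient {orphan[0]} absent from patient_dimension")
    unknown = conn.execute(
        "SELECT f.concept_cd FROM observation_fact f LEFT JOIN concept_dimension c"
        " ON f.concept_cd = c.concept_cd WHERE c.concept_cd IS NULL"
        " AND f.upload_id = ? LIMIT 1",
        (upload_id,),
    ).fetchone()
    if unknown:
        raise LoadError(f"fact concept {unknown[0]!r} missing from concept_dimension")


# ---------------------------------------------------------------------------
# verification


def count_value_cells(
    source: sqlite3.Connection, meta: TableMeta, tclass: TableClass
) -> int:
    """Count the non-null value cells of one source table.

    For EAV-ready tables this is the number of rows with a non-null value
    column; for wide tables it is the sum of non-null VALUE/FREE_TEXT cells
    — exactly the number of facts the transform must emit.
    """
    if tclass.structure_type is StructureType.EAV_READY:
        vcol = meta.first_with_role(Role.VALUE)
        return source.execute(
            f'SELECT COUNT("{vcol.name}") FROM "{meta.name}"'
        ).fetchone()[0]
    cells = [c.name for c in meta.columns if c.role in (Role.VALUE, Role.FREE_TEXT)]
    if not cells:
        return 0
    expr = " + ".join(f'COUNT("{c}")' for c in cells)
    return source.execute(f'SELECT {expr} FROM "{meta.name}"').fetchone()[0]


def verify_counts(
    source_counts: Mapping[str, int],
    star: StarDatabase,
    skipped: Sequence[str] = (),
) -> VerificationReport:
    """Compare per-source-table value-cell counts with loaded fact counts."""
    loaded = dict(
        star.conn.execute(
            "SELECT sourcesystem_cd, COUNT(*) FROM observation_fact"
            " WHERE upload_id = ? GROUP BY sourcesystem_cd",
            (star.upload_id,),
        )
    )
    per_table = {}
    for table, src_count in sorted(source_counts.items()):
        got = loaded.get(table, 0)
        per_table[table] = (src_count, got, src_count == got)
    for table, got in loaded.items():
        if table not in per_table:
            per_table[table] = (0, got, False)
    report = VerificationReport(per_table=per_table, skipped=list(skipped))
    if not report.overall_equal:
        log.warning("count verification failed:\n%s", report.summary())
    return report


# ---------------------------------------------------------------------------
# CSV export


def export_csv(star: StarDatabase, outdir: Path | str) -> list[Path]:
    """Export every star table as RFC-4180 CSV with a header row."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for table in STAR_TABLES:
        cur = star.conn.execute(f'SELECT * FROM "{table}" ORDER BY rowid')
        cols = [d[0] for d in cur.description]
        dest = outdir / f"{table}.csv"
        with dest.open("w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(cols)
            writer.writerows(cur)
        written.append(dest)
    return written
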