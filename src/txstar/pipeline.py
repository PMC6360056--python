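"""End-to-end ETL orchestration.

Stage order: read → classify → denormalization views → encounter assignment
→ [rotate | passthrough] → value encoding → instance stamping → ontology →
star load → count verification. EAV-ready tables bypass the rotation stage
entirely (the stage counters prove it); everything streams in chunks so the
resident fact buffer is bounded by the chunk size.

Re-running with the same config replaces that run's rows (upload-id
semantics). Warnings (dropped join rows, skipped tables) are never fatal;
stage errors always are.
"""

from __future__ import annotations

import csv
import datetime as dt
import json
import logging
import sqlite3
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Optional, Union

from . import eav, views
from .encounters import SurrogateRegistry, TransplantRecord, build_timeframes, assign_encounter_with_rule
from .eav import InstanceMode, ObservationFact
from .ontology import ConceptRecord, build_ontology
from .schema import (
    Role,
    SourceSchema,
    StructureType,
    TableClass,
    UnclassifiableTableError,
    classify_table,
    load_schema,
)
from .star import StarDatabase, count_value_cells, load, verify_counts

__all__ = ["RunConfig", "RunReport", "run_etl", "open_source"]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    source: Union[str, Path]                 # SQLite file or CSV directory
    schema: Union[str, Path, Mapping]        # schema/role-map config
    target: Union[str, Path]                 # star database file
    instance_mode: InstanceMode = InstanceMode.GROUPED
    chunk_size: int = views.DEFAULT_CHUNK_SIZE
    concept_prefix: str = "SRC"
    upload_id: int = 1
    failure_column: Optional[str] = "failure_date"
    audit_path: Optional[Union[str, Path]] = None
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.chunk_size < 1:
            raise ValueError("chunk size must be >= 1")


@dataclass
class TableReport:
    structure_type: str
    data_flags: list[str]
    rows_read: int = 0
    rows_dropped: int = 0
    facts_rotated: int = 0
    facts_passthrough: int = 0
    rotation_stage_executed: bool = False

    @property
    def facts_emitted(self) -> int:
        return self.facts_rotated + self.facts_passthrough


@dataclass
class RunReport:
    per_table: dict[str, TableReport]
    skipped_tables: list[str]
    warnings: list[str]
    verification: dict
    stage_seconds: dict[str, float]
    total_facts: int
    encounter_rules: dict[str, int]

    @property
    def overall_equal(self) -> bool:
        return bool(self.verification.get("overall_equal"))

    def to_dict(self) -> dict:
        return {
            "per_table": {
                t: {
                    "structure_type": r.structure_type,
                    "data_flags": sorted(r.data_flags),
                    "rows_read": r.rows_read,
                    "rows_dropped": r.rows_dropped,
                    "facts_rotated": r.facts_rotated,
                    "facts_passthrough": r.facts_passthrough,
                    "rotation_stage_executed": r.rotation_stage_executed,
                }
                for t, r in sorted(self.per_table.items())
            },
            "skipped_tables": sorted(self.skipped_tables),
            "warnings": list(self.warnings),
            "verification": self.verification,
            "stage_seconds": {k: round(v, 3) for k, v in self.stage_seconds.items()},
            "total_facts": self.total_facts,
            "encounter_rules": dict(sorted(self.encounter_rules.items())),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1)


def open_source(source: Union[str, Path], schema_cfg: Optional[Mapping] = None) -> sqlite3.Connection:
    """Open a source: a SQLite file, or a CSV directory loaded into memory.

    CSV tables are created with the header's columns (TEXT affinity) and
    filled chunk-wise; empty strings become NULL.
    """
    source = Path(source)
    if source.is_dir():
        conn = sqlite3.connect(":memory:")
        for path in sorted(source.glob("*.csv")):
            table = path.stem
            with path.open(newline="") as fh:
                reader = csv.reader(fh)
                header = next(reader)
                cols = ", ".join(f'"{c}"' for c in header)
                conn.execute(f'CREATE TABLE "{table}" ({cols})')
                sql = (
                    f'INSERT INTO "{table}" VALUES ({", ".join("?" * len(header))})'
                )
                chunk = []
                for row in reader:
                    chunk.append([None if v == "" else v for v in row])
                    if len(chunk) >= 50_000:
                        conn.executemany(sql, chunk)
                        chunk.clear()
                if chunk:
                    conn.executemany(sql, chunk)
        conn.commit()
        return conn
    if not source.exists():
        raise FileNotFoundError(source)
    return sqlite3.connect(str(source))


def _timeframes_and_registry(
    schema: SourceSchema, conn: sqlite3.Connection, failure_column: Optional[str]
):
    anchor = schema.anchor
    pk = anchor.primary_key[0]
    patient_col = schema.anchor_patient_fk().column
    date_col = anchor.first_with_role(Role.DATE)
    if date_col is None:
        raise ValueError(f"anchor table {anchor.name} has no DATE column")
    has_failure = failure_column and any(c.name == failure_column for c in anchor.columns)
    fail_expr = f', "{failure_column}"' if has_failure else ", NULL"
    rows = conn.execute(
        f'SELECT "{patient_col}", "{pk}", "{date_col.name}"{fail_expr} '
        f'FROM "{anchor.name}" ORDER BY "{patient_col}", "{date_col.name}"'
    ).fetchall()
    per_patient: dict[int, list[TransplantRecord]] = {}
    for pid, tid, d, f in rows:
        per_patient.setdefault(int(pid), []).append(
            TransplantRecord(
                transplant_id=int(tid),
                date=dt.date.fromisoformat(str(d)[:10]),
                failure_date=dt.date.fromisoformat(str(f)[:10]) if f else None,
            )
        )
    timeframes = {pid: build_timeframes(pid, recs) for pid, recs in per_patient.items()}

    patient_pk = schema.tables[schema.patient_table].primary_key[0]
    all_patients = [
        int(r[0])
        for r in conn.execute(f'SELECT "{patient_pk}" FROM "{schema.patient_table}"')
    ]
    registry = SurrogateRegistry(
        {pid: len(timeframes.get(pid, ())) for pid in all_patients}
    )
    return timeframes, registry


def run_etl(config: RunConfig) -> RunReport:
    """Run the full pipeline and return the run report.

    The report's stage counts are mutually consistent: every fact leaving
    the encode stage is loaded, and the verification section reconciles
    loaded facts against the source's non-null value cells.
    """
    logging.basicConfig(level=config.log_level)
    t0 = time.perf_counter()
    stage_seconds: dict[str, float] = {}
    warnings: list[str] = []

    conn = open_source(config.source)
    schema_cfg = config.schema
    schema = load_schema(schema_cfg, source=conn)
    stage_seconds["read"] = time.perf_counter() - t0

    # classification -------------------------------------------------------
    t1 = time.perf_counter()
    classes: dict[str, TableClass] = {}
    skipped: list[str] = []
    for name in schema.tables:
        if name == schema.patient_table:
            continue
        try:
            classes[name] = classify_table(schema, name)
        except UnclassifiableTableError as exc:
            skipped.append(name)
            warnings.append(str(exc))
            log.warning("skipping table %s: %s", name, exc)
    stage_seconds["classify"] = time.perf_counter() - t1

    # encounter scaffolding -------------------------------------------------
    t2 = time.perf_counter()
    timeframes, registry = _timeframes_and_registry(schema, conn, config.failure_column)
    stage_seconds["timeframes"] = time.perf_counter() - t2

    per_table: dict[str, TableReport] = {
        name: TableReport(
            structure_type=c.structure_type.value,
            data_flags=[f.value for f in c.data_flags],
        )
        for name, c in classes.items()
    }
    concepts: set[ConceptRecord] = set()
    rule_counts: dict[str, int] = {}
    audit_rows: list[tuple] = []
    audit = config.audit_path is not None

    def fact_stream() -> Iterator[ObservationFact]:
        for name, tclass in classes.items():
            meta = schema.tables[name]
            report = per_table[name]
            view = views.build_view(schema, name, tclass)
            mat = views.materialize(view, conn, config.chunk_size)
            date_col = meta.first_with_role(Role.DATE)
            for row in mat.rows():
                report.rows_read += 1
                # encounter assignment for rows the join could not supply
                if view.has_encounter:
                    rule = "LINKED"
                else:
                    pid = int(row[views.PATIENT_KEY])
                    fdate = dt.date.fromisoformat(str(row[date_col.name])[:10])
                    enc, rule = assign_encounter_with_rule(
                        pid, fdate, timeframes.get(pid, ()), registry
                    )
                    row[views.ENCOUNTER_KEY] = enc
                rule_counts[rule] = rule_counts.get(rule, 0) + 1

                if tclass.structure_type is StructureType.EAV_READY:
                    pre_rows = eav.passthrough([row], meta, config.concept_prefix)
                    report.facts_passthrough += len(pre_rows)
                else:
                    report.rotation_stage_executed = True
                    pre_rows = eav.rotate_row(row, meta, tclass, config.concept_prefix)
                    report.facts_rotated += len(pre_rows)
                for pre in pre_rows:
                    concepts.add(_concept_record(pre, meta, config.concept_prefix))
                    if audit:
                        audit_rows.append(
                            (pre.source_event_key, pre.patient_id,
                             pre.date.isoformat(), pre.encounter_id, rule)
                        )
                    yield eav.make_fact(pre, upload_id=config.upload_id)
            if mat.rows_dropped:
                report.rows_dropped = mat.rows_dropped
                warnings.append(
                    f"table {name}: {mat.rows_dropped} rows dropped (dangling foreign keys)"
                )

    # patients --------------------------------------------------------------
    pmeta = schema.tables[schema.patient_table]
    ppk = pmeta.primary_key[0]
    pcols = [c.name for c in pmeta.columns]
    patient_rows = []
    for row in conn.execute(f'SELECT {", ".join(pcols)} FROM "{schema.patient_table}"'):
        d = dict(zip(pcols, row))
        patient_rows.append(
            {
                "patient_num": d[ppk],
                "birth_date": d.get("birth_date"),
                "sex_cd": d.get("sex"),
                "sourcesystem_cd": schema.patient_table,
            }
        )

    # transform + load -------------------------------------------------------
    t3 = time.perf_counter()
    star = load(
        fact_stream(),
        patient_rows,
        lambda: build_ontology(concepts, prefix=config.concept_prefix),
        config.target,
        instance_mode=config.instance_mode,
        upload_id=config.upload_id,
        chunk_size=config.chunk_size,
    )
    stage_seconds["transform_load"] = time.perf_counter() - t3

    if audit:
        with Path(config.audit_path).open("w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["source_event_key", "patient_id", "date", "encounter_id", "rule"])
            w.writerows(audit_rows)

    # verification -----------------------------------------------------------
    t4 = time.perf_counter()
    source_counts = {
        name: count_value_cells(conn, schema.tables[name], tclass)
        for name, tclass in classes.items()
    }
    report = verify_counts(source_counts, star, skipped=skipped)
    stage_seconds["verify"] = time.perf_counter() - t4
    star.close()
    conn.close()

    total_facts = sum(r.facts_emitted for r in per_table.values())
    return RunReport(
        per_table=per_table,
        skipped_tables=skipped,
        warnings=warnings,
        verification=report.to_dict(),
        stage_seconds=stage_seconds,
        total_facts=total_facts,
        encounter_rules=rule_counts,
    )


def _concept_record(pre: eav.PreEavRow, meta, prefix: str) -> ConceptRecord:
    parts = pre.concept_code.split(":")
    # prefix:table:X for EAV concept values and plain columns,
    # prefix:table:col:value for categorical column values
    if len(parts) == 3:
        table, tail = parts[1], parts[2]
        if meta.first_with_role(Role.CONCEPT) is not None:
            return ConceptRecord(table=table, column=None, value=tail, code=pre.concept_code)
        return ConceptRecord(table=table, column=tail, value=None, code=pre.concept_code)
    return ConceptRecord(table=parts[1], column=parts[2], value=parts[3], code=pre.concept_code)
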