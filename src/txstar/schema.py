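"""Source-schema description, foreign-key traversal and table classification.

A relational transplant EHR is described by a :class:`SourceSchema`: every
table with its columns, each column annotated with a semantic *role*, plus the
primary/foreign keys. The schema singles out an *anchor* table (the
transplantation table, the central entity of the source) and the patient
table.

Each table is classified along two axes:

* structure — whether its rows are already one-fact-per-row EAV
  (``EAV_READY``), reach the anchor through a chain of foreign keys
  (``ANCHOR_LINKED``), or carry no reference to the anchor at all
  (``UNLINKED``, to be resolved later by temporal windows);
* data — whether it carries free-text blobs (``FREE_TEXT_BLOB``) and/or
  numeric values with associated units (``UNIT_BEARING``).

Roles are declared in a config file (YAML/JSON), not inferred from data: the
semantic mapping of a clinical schema is a domain-expert decision, not a
profiling result.
"""

from __future__ import annotations

import json
import sqlite3
from collections import deque
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import yaml

__all__ = [
    "Role",
    "StructureType",
    "DataFlag",
    "ColumnMeta",
    "ForeignKey",
    "TableMeta",
    "SourceSchema",
    "TableClass",
    "ConfigError",
    "SchemaError",
    "UnclassifiableTableError",
    "load_schema",
    "fk_path",
    "classify_table",
]


class ConfigError(ValueError):
    """Invalid or incomplete schema/role-map configuration."""


class SchemaError(ValueError):
    """Structurally inconsistent schema (dangling FK targets, bad keys)."""


class UnclassifiableTableError(SchemaError):
    """Table carries no patient reference and no FK path toward one."""


class Role(str, Enum):
    PATIENT_REF = "PATIENT_REF"
    ENCOUNTER_REF = "ENCOUNTER_REF"
    DATE = "DATE"
    VALUE = "VALUE"
    UNIT = "UNIT"
    FREE_TEXT = "FREE_TEXT"
    CONCEPT = "CONCEPT"      # generic concept column of an EAV-ready table
    EVENT_KEY = "EVENT_KEY"  # groups rows recorded at one and the same event
    KEY = "KEY"              # primary/foreign key column
    METADATA = "METADATA"


class StructureType(str, Enum):
    EAV_READY = "EAV_READY"          # type 1
    ANCHOR_LINKED = "ANCHOR_LINKED"  # type 2
    UNLINKED = "UNLINKED"            # type 3


class DataFlag(str, Enum):
    FREE_TEXT_BLOB = "FREE_TEXT_BLOB"  # type 4
    UNIT_BEARING = "UNIT_BEARING"      # type 5


@dataclass(frozen=True)
class ColumnMeta:
    """One source column and its semantic role.

    ``numeric`` marks VALUE columns whose content must parse as a number
    (unparseable text is an error, never silently coerced); ``categorical``
    marks low-cardinality coded VALUE columns whose concept codes embed the
    value; ``unit_of`` names, on a UNIT column, the VALUE column it
    qualifies.
    """

    name: str
    role: Role = Role.METADATA
    nullable: bool = True
    numeric: bool = False
    categorical: bool = False
    unit_of: Optional[str] = None


@dataclass(frozen=True)
class ForeignKey:
    column: str
    ref_table: str
    ref_column: str

    def __str__(self) -> str:  # used in error messages
        return f"{self.column} -> {self.ref_table}.{self.ref_column}"


@dataclass
class TableMeta:
    """A source table: ordered columns, keys, and the x/y column counts.

    ``n_columns`` (x) is the total column count and ``n_metadata`` (y) the
    count of non-value columns; a wide row rotates into at most x − y
    entity-attribute-value lines.
    """

    name: str
    columns: list[ColumnMeta]
    primary_key: list[str] = field(default_factory=list)
    foreign_keys: list[ForeignKey] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [c.name for c in self.columns]
        if len(set(names)) != len(names):
            raise SchemaError(f"table {self.name}: duplicate column names")
        for pk in self.primary_key:
            if pk not in names:
                raise SchemaError(f"table {self.name}: primary key column {pk!r} not declared")
        for fk in self.foreign_keys:
            if fk.column not in names:
                raise SchemaError(f"table {self.name}: foreign key column {fk.column!r} not declared")

    @property
    def n_columns(self) -> int:
        return len(self.columns)

    @property
    def n_metadata(self) -> int:
        return sum(1 for c in self.columns if c.role not in (Role.VALUE, Role.FREE_TEXT))

    def column(self, name: str) -> ColumnMeta:
        for c in self.columns:
            if c.name == name:
                return c
        raise KeyError(name)

    def columns_with_role(self, role: Role) -> list[ColumnMeta]:
        return [c for c in self.columns if c.role is role]

    def first_with_role(self, role: Role) -> Optional[ColumnMeta]:
        cols = self.columns_with_role(role)
        return cols[0] if cols else None


@dataclass
class SourceSchema:
    tables: dict[str, TableMeta]
    anchor_table: str
    patient_table: str

    def __post_init__(self) -> None:
        if not self.tables:
            raise ConfigError("schema declares no tables")
        if self.anchor_table not in self.tables:
            raise ConfigError(f"anchor table {self.anchor_table!r} not among declared tables")
        if self.patient_table not in self.tables:
            raise ConfigError(f"patient table {self.patient_table!r} not among declared tables")
        for t in self.tables.values():
            for fk in t.foreign_keys:
                if fk.ref_table not in self.tables:
                    raise SchemaError(
                        f"table {t.name}: foreign key {fk} references unknown table {fk.ref_table!r}"
                    )
        anchor = self.tables[self.anchor_table]
        if not any(fk.ref_table == self.patient_table for fk in anchor.foreign_keys):
            raise SchemaError(
                f"anchor table {self.anchor_table!r} has no foreign key to patient table"
            )

    @property
    def anchor(self) -> TableMeta:
        return self.tables[self.anchor_table]

    def anchor_patient_fk(self) -> ForeignKey:
        for fk in self.anchor.foreign_keys:
            if fk.ref_table == self.patient_table:
                return fk
        raise SchemaError("anchor has no patient FK")  # unreachable after validation


@dataclass(frozen=True)
class TableClass:
    """Structure type plus data flags plus the FK path to the anchor.

    ``fk_path`` is ``None`` when no path exists; the empty tuple is the
    anchor's own identity path.
    """

    structure_type: StructureType
    data_flags: frozenset[DataFlag]
    fk_path: Optional[tuple[ForeignKey, ...]]


# ---------------------------------------------------------------------------
# schema loading


def _parse_column(spec: Mapping) -> ColumnMeta:
    try:
        role = Role(spec.get("role", "METADATA"))
    except ValueError as exc:
        raise ConfigError(f"column {spec.get('name')!r}: unknown role {spec.get('role')!r}") from exc
    return ColumnMeta(
        name=spec["name"],
        role=role,
        nullable=bool(spec.get("nullable", True)),
        numeric=bool(spec.get("numeric", False)),
        categorical=bool(spec.get("categorical", False)),
        unit_of=spec.get("unit_of"),
    )


def _parse_fk(spec: Mapping, table: str) -> ForeignKey:
    ref = spec.get("references", "")
    if "." not in ref:
        raise ConfigError(f"table {table}: foreign key reference {ref!r} must be 'table.column'")
    ref_table, ref_column = ref.split(".", 1)
    return ForeignKey(column=spec["column"], ref_table=ref_table, ref_column=ref_column)


def load_schema(
    config: Union[str, Path, Mapping],
    source: Optional[sqlite3.Connection] = None,
) -> SourceSchema:
    """Load and validate a schema/role-map config (YAML/JSON path or dict).

    When a live SQLite source is given, every declared table and column must
    exist in it; columns present in the database but undeclared in the config
    are appended with role METADATA.
    """
    if isinstance(config, (str, Path)):
        text = Path(config).read_text()
        if str(config).endswith(".json"):
            config = json.loads(text)
        else:
            config = yaml.safe_load(text)
    if not isinstance(config, Mapping):
        raise ConfigError("schema config must be a mapping")
    tables_cfg = config.get("tables") or {}
    if not tables_cfg:
        raise ConfigError("schema declares no tables")
    for key in ("anchor_table", "patient_table"):
        if not config.get(key):
            raise ConfigError(f"schema config missing {key}")

    tables: dict[str, TableMeta] = {}
    for name, tcfg in tables_cfg.items():
        columns = [_parse_column(c) for c in tcfg.get("columns", [])]
        pk = tcfg.get("primary_key", [])
        if isinstance(pk, str):
            pk = [pk]
        fks = [_parse_fk(f, name) for f in tcfg.get("foreign_keys", [])]
        if len(pk) > 1:
            raise ConfigError(f"table {name}: composite primary keys are unsupported")
        tables[name] = TableMeta(name=name, columns=columns, primary_key=list(pk), foreign_keys=fks)

    if source is not None:
        _check_against_live(tables, source)

    return SourceSchema(
        tables=tables,
        anchor_table=config["anchor_table"],
        patient_table=config["patient_table"],
    )


def _check_against_live(tables: dict[str, TableMeta], conn: sqlite3.Connection) -> None:
    existing = {
        r[0] for r in conn.execute("SELECT name FROM sqlite_master WHERE type IN ('table','view')")
    }
    for name, meta in tables.items():
        if name not in existing:
            raise SchemaError(f"declared table {name!r} does not exist in the source database")
        live_cols = [r[1] for r in conn.execute(f'PRAGMA table_info("{name}")')]
        declared = {c.name for c in meta.columns}
        missing = declared - set(live_cols)
        if missing:
            raise SchemaError(f"table {name!r}: declared columns missing in source: {sorted(missing)}")
        for col in live_cols:
            if col not in declared:
                meta.columns.append(ColumnMeta(name=col, role=Role.METADATA))


# ---------------------------------------------------------------------------
# FK traversal and classification


def fk_path(
    schema: SourceSchema, table: str, anchor: Optional[str] = None
) -> Optional[tuple[ForeignKey, ...]]:
    """Shortest directed FK path from ``table`` to the anchor, or ``None``.

    Breadth-first over the FK graph; ties are broken by lexicographic order
    of (local column, target table). The anchor itself yields the empty
    path. Cycles are handled with a visited set.
    """
    anchor = anchor or schema.anchor_table
    if table not in schema.tables:
        raise KeyError(table)
    if anchor not in schema.tables:
        raise KeyError(anchor)
    if table == anchor:
        return ()
    visited = {table}
    queue: deque[tuple[str, tuple[ForeignKey, ...]]] = deque([(table, ())])
    while queue:
        current, path = queue.popleft()
        hops = sorted(
            schema.tables[current].foreign_keys,
            key=lambda fk: (fk.column, fk.ref_table),
        )
        for fk in hops:
            if fk.ref_table == anchor:
                return path + (fk,)
            if fk.ref_table not in visited:
                visited.add(fk.ref_table)
                queue.append((fk.ref_table, path + (fk,)))
    return None


def _has_patient_access(schema: SourceSchema, table: str, seen: Optional[set] = None) -> bool:
    """True if the table has a PATIENT_REF column or reaches one via FKs."""
    seen = seen or set()
    if table in seen:
        return False
    seen.add(table)
    meta = schema.tables[table]
    if meta.first_with_role(Role.PATIENT_REF) is not None:
        return True
    if table == schema.patient_table:
        return True
    return any(
        fk.ref_table in schema.tables and _has_patient_access(schema, fk.ref_table, seen)
        for fk in meta.foreign_keys
    )


def _is_eav_ready(meta: TableMeta) -> bool:
    has_patient = meta.first_with_role(Role.PATIENT_REF) is not None
    has_date = meta.first_with_role(Role.DATE) is not None
    has_concept = meta.first_with_role(Role.CONCEPT) is not None
    has_value = bool(meta.columns_with_role(Role.VALUE))
    return has_patient and has_date and has_concept and has_value


def classify_table(schema: SourceSchema, table: str) -> TableClass:
    """Classify one table into a structure type plus data flags.

    EAV_READY takes precedence over linkage; ANCHOR_LINKED requires an FK
    path to the anchor (the anchor's identity path counts); UNLINKED
    requires at least a direct patient reference and a date.
    """
    meta = schema.tables[table]
    path = fk_path(schema, table)

    flags = set()
    if meta.columns_with_role(Role.FREE_TEXT):
        flags.add(DataFlag.FREE_TEXT_BLOB)
    unit_cols = meta.columns_with_role(Role.UNIT)
    if unit_cols:
        value_cols = meta.columns_with_role(Role.VALUE)
        paired = any(
            (u.unit_of is None and any(v.numeric for v in value_cols))
            or (u.unit_of is not None and any(v.name == u.unit_of and v.numeric for v in value_cols))
            for u in unit_cols
        )
        if paired:
            flags.add(DataFlag.UNIT_BEARING)

    if _is_eav_ready(meta):
        stype = StructureType.EAV_READY
    elif path is not None:
        stype = StructureType.ANCHOR_LINKED
    elif meta.first_with_role(Role.PATIENT_REF) is not None:
        stype = StructureType.UNLINKED
    else:
        if not _has_patient_access(schema, table):
            raise UnclassifiableTableError(
                f"table {table!r} has no patient reference and no FK path to one"
            )
        raise UnclassifiableTableError(
            f"table {table!r} reaches a patient reference only through tables "
            "that do not reach the anchor; cannot assign encounters"
        )

    return TableClass(structure_type=stype, data_flags=frozenset(flags), fk_path=path)
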