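"""Entity-attribute-value transformation into i2b2 observation facts.

Wide source rows are *rotated*: every non-null value or free-text cell of a
row becomes one pre-EAV line, so a row with x columns of which y are
metadata yields at most x − y lines. Tables already in one-fact-per-row EAV
shape *pass through* without rotation. Values are then encoded into the
i2b2 fact-table value columns (numeric → NVAL_NUM with TVAL_CHAR "E",
free-text blob → OBSERVATION_BLOB, anything else → TVAL_CHAR), units go to
UNITS_CD, and facts recorded at one and the same source event receive a
shared INSTANCE_NUM.

Null cells emit no fact: the EAV store holds present observations only, and
"value is not set" queries are answered by concept absence downstream. This
is also what makes the count-conservation verification exact.

Concept codes follow the deterministic scheme
``<prefix>:<table>:<column>[:<value>]`` for rotated tables and
``<prefix>:<table>:<concept value>`` for EAV-ready tables.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

from .schema import ColumnMeta, DataFlag, Role, StructureType, TableClass, TableMeta

__all__ = [
    "InstanceMode",
    "PreEavRow",
    "ObservationFact",
    "MalformedRowError",
    "EncodingError",
    "rotate_row",
    "passthrough",
    "encode_value",
    "make_fact",
    "assign_instance_nums",
    "concept_code",
]

DEFAULT_PROVIDER = "@"
DEFAULT_MODIFIER = "@"


class MalformedRowError(ValueError):
    """Source row lacking a mandatory fact attribute."""


class EncodingError(ValueError):
    """A declared-numeric value failed to parse as a number."""


class InstanceMode(str, Enum):
    #: facts sharing (patient, encounter, source event) share one instance
    #: number — enables "collected at one and the same event" queries.
    GROUPED = "GROUPED"
    #: every fact gets a fresh incremented value, reproducing the limitation
    #: of the legacy loader ("just uses an incremented value").
    IDRT_COMPAT = "IDRT_COMPAT"


@dataclass
class PreEavRow:
    """One pre-EAV line: the minimal attributes of a single fact."""

    patient_id: int
    encounter_id: int
    date: dt.date
    concept_code: str
    raw_value: object
    unit: Optional[str] = None
    is_blob: bool = False
    numeric: bool = False
    categorical: bool = False
    source_event_key: str = ""
    source_table: str = ""


@dataclass
class ObservationFact:
    """One row of the i2b2 OBSERVATION_FACT table (1.7 column subset).

    ``sourcesystem_cd`` records the originating source table and
    ``source_event_key`` the originating source event — both are what the
    count-conservation verification and event-grouped queries key on.
    """

    encounter_num: int
    patient_num: int
    concept_cd: str
    start_date: dt.date
    provider_id: str = DEFAULT_PROVIDER
    modifier_cd: str = DEFAULT_MODIFIER
    instance_num: int = 1
    valtype_cd: str = "T"
    tval_char: Optional[str] = None
    nval_num: Optional[float] = None
    units_cd: Optional[str] = None
    observation_blob: Optional[str] = None
    sourcesystem_cd: str = ""
    source_event_key: str = ""
    upload_id: int = 1

    def key(self) -> tuple:
        return (
            self.encounter_num,
            self.patient_num,
            self.concept_cd,
            self.provider_id,
            self.start_date,
            self.modifier_cd,
            self.instance_num,
        )


def _is_null(value: object) -> bool:
    return value is None or (isinstance(value, str) and value == "")


def concept_code(
    prefix: str, table: str, column: Optional[str] = None, value: Optional[object] = None
) -> str:
    parts = [prefix, table]
    if column is not None:
        parts.append(column)
    if value is not None:
        parts.append(str(value))
    return ":".join(parts)


# ---------------------------------------------------------------------------
# rotation and passthrough


def rotate_row(
    row: Mapping[str, object],
    meta: TableMeta,
    tclass: TableClass,
    concept_prefix: str,
    *,
    patient_key: str = "_patient",
    encounter_key: str = "_encounter",
    date_column: Optional[str] = None,
    event_key: Optional[str] = None,
) -> list[PreEavRow]:
    """Rotate one materialized view row into pre-EAV lines.

    One line per non-null VALUE/FREE_TEXT cell; categorical columns embed
    the cell value in the concept code; all lines share one source event
    key (the base row is one documentation event).
    """
    if tclass.structure_type is StructureType.EAV_READY:
        raise ValueError(f"table {meta.name} is EAV-ready; use passthrough()")
    patient = row.get(patient_key)
    date_col = date_column or (meta.first_with_role(Role.DATE) and meta.first_with_role(Role.DATE).name)
    date_val = row.get(date_col) if date_col else None
    if _is_null(patient) or _is_null(date_val):
        raise MalformedRowError(
            f"table {meta.name}, row {event_key or row}: missing patient reference or date"
        )
    encounter = row.get(encounter_key)
    date = _as_date(date_val)
    key = event_key or f"{meta.name}:{_pk_value(row, meta)}"

    units = {c.unit_of: c.name for c in meta.columns_with_role(Role.UNIT) if c.unit_of}
    default_unit_col = None
    unit_cols = meta.columns_with_role(Role.UNIT)
    if len(unit_cols) == 1 and unit_cols[0].unit_of is None:
        numeric_vals = [c for c in meta.columns_with_role(Role.VALUE) if c.numeric]
        if len(numeric_vals) == 1:
            default_unit_col = (numeric_vals[0].name, unit_cols[0].name)

    out: list[PreEavRow] = []
    for col in meta.columns:
        if col.role not in (Role.VALUE, Role.FREE_TEXT):
            continue
        value = row.get(col.name)
        if _is_null(value):
            continue
        is_blob = col.role is Role.FREE_TEXT
        if col.categorical and not is_blob:
            code = concept_code(concept_prefix, meta.name, col.name, value)
        else:
            code = concept_code(concept_prefix, meta.name, col.name)
        unit = None
        unit_col = units.get(col.name)
        if unit_col is None and default_unit_col and default_unit_col[0] == col.name:
            unit_col = default_unit_col[1]
        if unit_col is not None:
            uval = row.get(unit_col)
            unit = None if _is_null(uval) else str(uval)
        out.append(
            PreEavRow(
                patient_id=int(patient),
                encounter_id=int(encounter) if not _is_null(encounter) else None,
                date=date,
                concept_code=code,
                raw_value=value,
                unit=unit,
                is_blob=is_blob,
                numeric=col.numeric,
                categorical=col.categorical,
                source_event_key=key,
                source_table=meta.name,
            )
        )
    return out


def passthrough(
    rows: Iterable[Mapping[str, object]],
    meta: TableMeta,
    concept_prefix: str,
    *,
    patient_key: str = "_patient",
    encounter_key: str = "_encounter",
) -> list[PreEavRow]:
    """Map EAV-ready rows 1:1 onto pre-EAV lines without rotation.

    The concept code is taken from the source's concept column; rows sharing
    the source's event key (one lab test) share a source_event_key.
    """
    concept_col = meta.first_with_role(Role.CONCEPT)
    value_col = meta.first_with_role(Role.VALUE)
    date_col = meta.first_with_role(Role.DATE)
    unit_col = meta.first_with_role(Role.UNIT)
    event_col = meta.first_with_role(Role.EVENT_KEY)
    if concept_col is None or value_col is None or date_col is None:
        raise MalformedRowError(f"table {meta.name}: not EAV-ready (concept/value/date roles)")
    out: list[PreEavRow] = []
    for row in rows:
        concept_val = row.get(concept_col.name)
        if _is_null(concept_val):
            raise MalformedRowError(
                f"table {meta.name}, row {_pk_value(row, meta)}: missing concept value"
            )
        patient = row.get(patient_key, row.get("_patient"))
        if _is_null(patient):
            raise MalformedRowError(f"table {meta.name}: row missing patient reference")
        date_val = row.get(date_col.name)
        if _is_null(date_val):
            raise MalformedRowError(f"table {meta.name}: row missing date")
        if event_col is not None and not _is_null(row.get(event_col.name)):
            key = f"{meta.name}:{row[event_col.name]}"
        else:
            key = f"{meta.name}:{_pk_value(row, meta)}"
        unit = None
        if unit_col is not None:
            uval = row.get(unit_col.name)
            unit = None if _is_null(uval) else str(uval)
        encounter = row.get(encounter_key)
        out.append(
            PreEavRow(
                patient_id=int(patient),
                encounter_id=int(encounter) if not _is_null(encounter) else None,
                date=_as_date(date_val),
                concept_code=concept_code(concept_prefix, meta.name, str(concept_val)),
                raw_value=row.get(value_col.name),
                unit=unit,
                is_blob=False,
                numeric=value_col.numeric,
                categorical=False,
                source_event_key=key,
                source_table=meta.name,
            )
        )
    return out


# ---------------------------------------------------------------------------
# value encoding


def encode_value(pre: PreEavRow) -> dict:
    """Encode a pre-EAV raw value into i2b2 fact value fields.

    Numeric (and not blob, not categorical) → valtype N, NVAL_NUM set,
    TVAL_CHAR "E", UNITS_CD carried; blob → valtype B with OBSERVATION_BLOB;
    everything else → valtype T with TVAL_CHAR. A declared-numeric value
    that does not parse raises instead of being coerced.
    """
    if _is_null(pre.raw_value):
        raise EncodingError(f"{pre.source_event_key}: null value reached encoding")
    if pre.is_blob:
        return {
            "valtype_cd": "B",
            "tval_char": None,
            "nval_num": None,
            "units_cd": None,
            "observation_blob": str(pre.raw_value),
        }
    if pre.categorical:
        return {
            "valtype_cd": "T",
            "tval_char": str(pre.raw_value),
            "nval_num": None,
            "units_cd": None,
            "observation_blob": None,
        }
    parsed: Optional[float] = None
    if isinstance(pre.raw_value, (int, float)) and not isinstance(pre.raw_value, bool):
        parsed = float(pre.raw_value)
    else:
        try:
            parsed = float(str(pre.raw_value))
        except (TypeError, ValueError):
            parsed = None
    if parsed is None:
        if pre.numeric:
            raise EncodingError(
                f"{pre.source_event_key}: declared-numeric value {pre.raw_value!r} "
                "is not parseable"
            )
        return {
            "valtype_cd": "T",
            "tval_char": str(pre.raw_value),
            "nval_num": None,
            "units_cd": None,
            "observation_blob": None,
        }
    return {
        "valtype_cd": "N",
        "tval_char": "E",
        "nval_num": parsed,
        "units_cd": pre.unit,
        "observation_blob": None,
    }


def make_fact(pre: PreEavRow, upload_id: int = 1) -> ObservationFact:
    """Build an (instance-unstamped) observation fact from a pre-EAV line."""
    fields = encode_value(pre)
    return ObservationFact(
        encounter_num=pre.encounter_id,
        patient_num=pre.patient_id,
        concept_cd=pre.concept_code,
        start_date=pre.date,
        sourcesystem_cd=pre.source_table,
        source_event_key=pre.source_event_key,
        upload_id=upload_id,
        **fields,
    )


# ---------------------------------------------------------------------------
# instance numbers


def assign_instance_nums(
    facts: Sequence[ObservationFact], mode: InstanceMode = InstanceMode.GROUPED
) -> list[ObservationFact]:
    """Stamp instance numbers, returning facts in their input order.

    GROUPED: within each (patient, encounter), distinct source events are
    numbered 1.. ascending by (event date, event key) and every fact of an
    event shares its number. IDRT_COMPAT: a single global counter in input
    order, so co-recorded facts never share a number.
    """
    stamped: list[ObservationFact] = []
    if mode is InstanceMode.IDRT_COMPAT:
        for i, f in enumerate(facts, start=1):
            stamped.append(replace(f, instance_num=i))
        return stamped
    events: dict[tuple, dict[tuple, int]] = {}
    for f in facts:
        events.setdefault((f.patient_num, f.encounter_num), {}).setdefault(
            (f.start_date, f.source_event_key), 0
        )
    numbering: dict[tuple, int] = {}
    for group, evs in events.items():
        for n, ev in enumerate(sorted(evs), start=1):
            numbering[group + ev] = n
    for f in facts:
        n = numbering[(f.patient_num, f.encounter_num, f.start_date, f.source_event_key)]
        stamped.append(replace(f, instance_num=n))
    return stamped


# ---------------------------------------------------------------------------
# helpers


def _as_date(value: object) -> dt.date:
    if isinstance(value, dt.date) and not isinstance(value, dt.datetime):
        return value
    if isinstance(value, dt.datetime):
        return value.date()
    return dt.date.fromisoformat(str(value)[:10])


def _pk_value(row: Mapping[str, object], meta: TableMeta) -> object:
    if meta.primary_key:
        return row.get(meta.primary_key[0])
    return tuple(row.values())
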