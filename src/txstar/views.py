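"""Denormalization views: equip every table with the mandatory fact attributes.

A fact needs an encounter number, a patient identifier and a date. Tables
linked to the transplantation anchor get all three by joining along their FK
chain (the transplantation id becomes the encounter, the patient id is pulled
from the anchor); unlinked tables expose their own patient id and date and
leave the encounter to the timeframe assignment stage.

Joins are inner joins with explicit loss accounting: rows whose FK chain does
not resolve are counted and reported, never silently dropped — the downstream
count-conservation check depends on it.
"""

from __future__ import annotations

import logging
import sqlite3
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Optional

from .schema import Role, SourceSchema, StructureType, TableClass, TableMeta

__all__ = ["ViewDef", "Materializer", "build_view", "materialize", "DEFAULT_CHUNK_SIZE"]

log = logging.getLogger(__name__)

#: Rows held in memory at once while streaming a view.
DEFAULT_CHUNK_SIZE = 50_000

PATIENT_KEY = "_patient"
ENCOUNTER_KEY = "_encounter"


@dataclass
class ViewDef:
    """A join plan projecting one source table onto the mandatory attributes.

    The projected row carries every base-table column plus ``_patient`` and,
    for anchor-linked tables, ``_encounter`` (the transplantation id reached
    through the chain).
    """

    name: str
    base_table: str
    join_chain: tuple  # ordered FK hops (empty for unlinked / EAV-ready)
    has_encounter: bool
    select_sql: str
    order_column: str


def build_view(schema: SourceSchema, table: str, tclass: TableClass) -> ViewDef:
    """Build the denormalization view for one classified table.

    Anchor-linked tables join hop by hop up to the anchor; the anchor's own
    identity "chain" projects its primary key as the encounter. Unlinked and
    EAV-ready tables project their own patient column; tables that already
    expose every mandatory attribute pass through with an identity
    projection.
    """
    meta = schema.tables[table]
    if not meta.primary_key:
        raise ValueError(f"table {table}: a primary key is required for deterministic streaming")
    order_col = meta.primary_key[0]
    base_cols = ", ".join(f't0."{c.name}"' for c in meta.columns)

    chain = tclass.fk_path if tclass.fk_path is not None else ()
    anchor_linked = (
        tclass.structure_type is StructureType.ANCHOR_LINKED and tclass.fk_path is not None
    )

    if anchor_linked:
        anchor_meta = schema.anchor
        patient_fk = schema.anchor_patient_fk()
        anchor_pk = anchor_meta.primary_key[0]
        if not chain:
            # the anchor table itself: its PK is the encounter
            sql = (
                f'SELECT {base_cols}, t0."{patient_fk.column}" AS {PATIENT_KEY}, '
                f't0."{anchor_pk}" AS {ENCOUNTER_KEY} '
                f'FROM "{table}" t0 ORDER BY t0."{order_col}"'
            )
        else:
            joins = []
            prev = "t0"
            for i, fk in enumerate(chain, start=1):
                alias = f"t{i}"
                joins.append(
                    f'JOIN "{fk.ref_table}" {alias} ON {prev}."{fk.column}" = {alias}."{fk.ref_column}"'
                )
                prev = alias
            sql = (
                f'SELECT {base_cols}, {prev}."{patient_fk.column}" AS {PATIENT_KEY}, '
                f'{prev}."{anchor_pk}" AS {ENCOUNTER_KEY} '
                f'FROM "{table}" t0 {" ".join(joins)} ORDER BY t0."{order_col}"'
            )
        return ViewDef(
            name=f"v_{table}",
            base_table=table,
            join_chain=chain,
            has_encounter=True,
            select_sql=sql,
            order_column=order_col,
        )

    patient_col = meta.first_with_role(Role.PATIENT_REF)
    if patient_col is None:
        raise ValueError(f"table {table}: no patient reference column")
    sql = (
        f'SELECT {base_cols}, t0."{patient_col.name}" AS {PATIENT_KEY} '
        f'FROM "{table}" t0 ORDER BY t0."{order_col}"'
    )
    return ViewDef(
        name=f"v_{table}",
        base_table=table,
        join_chain=(),
        has_encounter=False,
        select_sql=sql,
        order_column=order_col,
    )


class Materializer:
    """Streams a view's joined rows in deterministic order, chunked.

    After the stream is exhausted, ``rows_emitted`` and ``rows_dropped``
    report the join-loss accounting (base rows whose FK chain dangles).
    """

    def __init__(
        self,
        view: ViewDef,
        conn: sqlite3.Connection,
        chunk_size: int = DEFAULT_CHUNK_SIZE,
    ):
        if chunk_size < 1:
            raise ValueError("chunk size must be >= 1")
        self.view = view
        self.conn = conn
        self.chunk_size = chunk_size
        self.rows_emitted = 0
        self.base_rows = conn.execute(
            f'SELECT COUNT(*) FROM "{view.base_table}"'
        ).fetchone()[0]
        self._done = False

    @property
    def rows_dropped(self) -> int:
        if not self._done:
            raise RuntimeError("stream not exhausted yet")
        return self.base_rows - self.rows_emitted

    def rows(self) -> Iterator[dict]:
        try:
            cur = self.conn.execute(self.view.select_sql)
        except sqlite3.Error as exc:
            raise RuntimeError(f"view {self.view.name} over {self.view.base_table}: {exc}") from exc
        cols = [d[0] for d in cur.description]
        while True:
            chunk = cur.fetchmany(self.chunk_size)
            if not chunk:
                break
            for row in chunk:
                self.rows_emitted += 1
                yield dict(zip(cols, row))
        self._done = True
        if self.rows_dropped:
            log.warning(
                "view %s: %d rows dropped (unresolvable join keys) of %d",
                self.view.name,
                self.rows_dropped,
                self.base_rows,
            )


def materialize(
    view: ViewDef, conn: sqlite3.Connection, chunk_size: int = DEFAULT_CHUNK_SIZE
) -> Materializer:
    return Materializer(view, conn, chunk_size)
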