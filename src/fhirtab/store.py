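"""The FHIR-compliant relational store.

Nine tables mirror the mapped resource content: a ``patient`` table with
``patient_telecom``/``patient_address`` child tables, one table per other
resource kind, and surrogate integer keys alongside the preserved FHIR
logical ids (the natural keys).  Reference columns come in pairs: the raw
target id (``*_ref_id``) and the resolved surrogate key (``*_key``), so an
unresolvable reference is an inspectable orphan rather than a lost row.

Backing engine: embedded SQLite reachable by URI (a path, ``sqlite:///path``
or ``:memory:``); the analytics layer speaks plain SQL against this handle.
"""

from __future__ import annotations

import sqlite3
from dataclasses import dataclass, field
from typing import Any

from .errors import MigrationRequiredError, StoreError
from .mapping import RowBatch
from .model import ReferenceView, ResourceType

PRIMARY_TABLE_FOR_TYPE: dict[ResourceType, str] = {
    ResourceType.PATIENT: "patient",
    ResourceType.ALLERGY_INTOLERANCE: "allergy",
    ResourceType.PRACTITIONER: "practitioner",
    ResourceType.CONDITION: "condition",
    ResourceType.SERVICE_REQUEST: "service_request",
    ResourceType.DIAGNOSTIC_REPORT: "diagnostic_report",
    ResourceType.APPOINTMENT: "appointment",
}


@dataclass(frozen=True)
class TableSpec:
    name: str
    columns: tuple[tuple[str, str], ...]  # (column, kind in text|date|integer|key)
    natural_key: tuple[str, ...] = ()
    foreign_keys: tuple[tuple[str, str], ...] = ()  # (key column, referenced table)
    # (key column, ref-id column, referenced table) pairs resolved after load
    reference_pairs: tuple[tuple[str, str, str], ...] = ()


def _spec(name, columns, natural_key=(), foreign_keys=(), reference_pairs=()):
    return TableSpec(
        name=name,
        columns=tuple(columns),
        natural_key=tuple(natural_key),
        foreign_keys=tuple(foreign_keys),
        reference_pairs=tuple(reference_pairs),
    )


SCHEMA_TABLES: dict[str, TableSpec] = {
    "patient": _spec(
        "patient",
        [
            ("logical_id", "text"),
            ("identifier", "text"),
            ("family", "text"),
            ("given", "text"),
            ("gender", "text"),
            ("birth_date", "date"),
            ("registration_date", "date"),
        ],
        natural_key=["logical_id"],
    ),
    "patient_telecom": _spec(
        "patient_telecom",
        [
            ("patient_key", "key"),
            ("patient_logical_id", "text"),
            ("system", "text"),
            ("value", "text"),
        ],
        foreign_keys=[("patient_key", "patient")],
        reference_pairs=[("patient_key", "patient_logical_id", "patient")],
    ),
    "patient_address": _spec(
        "patient_address",
        [
            ("patient_key", "key"),
            ("patient_logical_id", "text"),
            ("line", "text"),
            ("city", "text"),
            ("country", "text"),
        ],
        foreign_keys=[("patient_key", "patient")],
        reference_pairs=[("patient_key", "patient_logical_id", "patient")],
    ),
    "allergy": _spec(
        "allergy",
        [
            ("logical_id", "text"),
            ("identifier", "text"),
            ("clinical_status", "text"),
            ("code_display", "text"),
            ("patient_key", "key"),
            ("patient_ref_id", "text"),
        ],
        natural_key=["logical_id"],
        foreign_keys=[("patient_key", "patient")],
        reference_pairs=[("patient_key", "patient_ref_id", "patient")],
    ),
    "condition": _spec(
        "condition",
        [
            ("logical_id", "text"),
            ("identifier", "text"),
            ("clinical_status", "text"),
            ("category", "text"),
            ("code_display", "text"),
            ("patient_key", "key"),
            ("patient_ref_id", "text"),
        ],
        natural_key=["logical_id"],
        foreign_keys=[("patient_key", "patient")],
        reference_pairs=[("patient_key", "patient_ref_id", "patient")],
    ),
    "practitioner": _spec(
        "practitioner",
        [
            ("logical_id", "text"),
            ("identifier", "text"),
            ("family", "text"),
            ("given", "text"),
            ("city", "text"),
            ("qualification", "text"),
        ],
        natural_key=["logical_id"],
    ),
    "service_request": _spec(
        "service_request",
        [
            ("logical_id", "text"),
            ("identifier", "text"),
            ("status", "text"),
            ("category", "text"),
            ("code_display", "text"),
            ("authored_on", "date"),
            ("patient_key", "key"),
            ("patient_ref_id", "text"),
            ("requester_key", "key"),
            ("requester_ref_id", "text"),
            ("based_on_key", "key"),
            ("based_on_ref_id", "text"),
        ],
        natural_key=["logical_id"],
        foreign_keys=[
            ("patient_key", "patient"),
            ("requester_key", "practitioner"),
            ("based_on_key", "service_request"),
        ],
        reference_pairs=[
            ("patient_key", "patient_ref_id", "patient"),
            ("requester_key", "requester_ref_id", "practitioner"),
            ("based_on_key", "based_on_ref_id", "service_request"),
        ],
    ),
    "diagnostic_report": _spec(
        "diagnostic_report",
        [
            ("logical_id", "text"),
            ("identifier", "text"),
            ("status", "text"),
            ("category", "text"),
            ("code_display", "text"),
            ("patient_key", "key"),
            ("patient_ref_id", "text"),
            ("based_on_key", "key"),
            ("based_on_ref_id", "text"),
        ],
        natural_key=["logical_id"],
        foreign_keys=[
            ("patient_key", "patient"),
            ("based_on_key", "service_request"),
        ],
        reference_pairs=[
            ("patient_key", "patient_ref_id", "patient"),
            ("based_on_key", "based_on_ref_id", "service_request"),
        ],
    ),
    "appointment": _spec(
        "appointment",
        [
            ("logical_id", "text"),
            ("identifier", "text"),
            ("status", "text"),
            ("appointment_type", "text"),
            ("priority", "integer"),
            ("patient_key", "key"),
            ("patient_ref_id", "text"),
        ],
        natural_key=["logical_id"],
        foreign_keys=[("patient_key", "patient")],
        reference_pairs=[("patient_key", "patient_ref_id", "patient")],
    ),
}

# columns whose null-rate the integrity check reports (analytics depend on them)
_ANALYTIC_COLUMNS = [
    ("patient", "gender"),
    ("patient", "birth_date"),
    ("allergy", "code_display"),
    ("service_request", "code_display"),
    ("service_request", "authored_on"),
]

_SQL_TYPE = {"text": "TEXT", "date": "TEXT", "integer": "INTEGER", "key": "INTEGER"}


@dataclass
class SchemaHandle:
    store_uri: str
    tables: dict[str, TableSpec]
    conn: sqlite3.Connection = field(repr=False, default=None)


@dataclass
class IntegrityReport:
    orphans: dict[str, int] = field(default_factory=dict)  # "table.column" -> count
    orphan_rows: list[tuple[str, str, str]] = field(default_factory=list)
    duplicate_natural_keys: dict[str, int] = field(default_factory=dict)
    null_rates: dict[str, float] = field(default_factory=dict)

    @property
    def passing(self) -> bool:
        return not any(self.orphans.values()) and not any(
            self.duplicate_natural_keys.values()
        )


def _resolve_path(store_uri: str) -> str:
    if store_uri.startswith("sqlite:///"):
        return store_uri[len("sqlite:///"):]
    return store_uri


def _table_ddl(spec: TableSpec) -> str:
    cols = ["pk INTEGER PRIMARY KEY"]
    for name, kind in spec.columns:
        cols.append(f'"{name}" {_SQL_TYPE[kind]}')
    for col, ref_table in spec.foreign_keys:
        cols.append(f'FOREIGN KEY ("{col}") REFERENCES "{ref_table}"(pk)')
    return f'CREATE TABLE "{spec.name}" ({", ".join(cols)})'


def schema_ddl() -> str:
    """The full schema DDL, for inspection/export."""
    return ";\n".join(_table_ddl(s) for s in SCHEMA_TABLES.values()) + ";\n"


def create_schema(store_uri: str) -> SchemaHandle:
    """Create (or re-open) the nine-table schema; repeat-safe.

    A pre-existing table whose column set differs from the declared layout
    raises :class:`MigrationRequiredError`.
    """
    try:
        conn = sqlite3.connect(_resolve_path(store_uri))
    except sqlite3.Error as exc:
        raise StoreError(f"cannot open store {store_uri!r}: {exc}") from exc
    conn.execute("PRAGMA foreign_keys = OFF")  # keys resolved post-load
    for spec in SCHEMA_TABLES.values():
        existing = _existing_columns(conn, spec.name)
        if existing is None:
            conn.execute(_table_ddl(spec))
        else:
            declared = ["pk"] + [c for c, _ in spec.columns]
            if existing != declared:
                conn.close()
                raise MigrationRequiredError(
                    f"table {spec.name!r} exists with columns {existing}, "
                    f"expected {declared}"
                )
    conn.commit()
    return SchemaHandle(store_uri=store_uri, tables=dict(SCHEMA_TABLES), conn=conn)


def _existing_columns(conn, table: str) -> list[str] | None:
    rows = conn.execute(f'PRAGMA table_info("{table}")').fetchall()
    if not rows:
        return None
    return [r[1] for r in rows]


def _lookup_key(schema: SchemaHandle, table: str, logical_id: str) -> int | None:
    row = schema.conn.execute(
        f'SELECT pk FROM "{table}" WHERE logical_id = ?', (logical_id,)
    ).fetchone()
    return row[0] if row else None


def resolve_patient_key(schema: SchemaHandle, ref: ReferenceView) -> int | None:
    """Surrogate key of the patient with the referenced logical id (or None)."""
    if ref.target_type != ResourceType.PATIENT:
        raise StoreError(f"expected a Patient reference, got {ref.target_type.value}")
    return _lookup_key(schema, "patient", ref.target_id)


def resolve_practitioner_key(schema: SchemaHandle, ref: ReferenceView) -> int | None:
    if ref.target_type != ResourceType.PRACTITIONER:
        raise StoreError(
            f"expected a Practitioner reference, got {ref.target_type.value}"
        )
    return _lookup_key(schema, "practitioner", ref.target_id)


def _translate_row(schema: SchemaHandle, row: dict[str, Any]) -> dict[str, Any]:
    """Spread ReferenceView values into (key, ref-id) column pairs."""
    out: dict[str, Any] = {}
    for col, val in row.items():
        if isinstance(val, ReferenceView):
            base = col[:-4] if col.endswith("_ref") else col
            target_table = PRIMARY_TABLE_FOR_TYPE.get(val.target_type)
            out[f"{base}_ref_id"] = val.target_id
            out[f"{base}_key"] = (
                _lookup_key(schema, target_table, val.target_id)
                if target_table
                else None
            )
        else:
            out[col] = val
    return out


def load_rows(
    schema: SchemaHandle, batch: RowBatch, mode: str = "upsert"
) -> dict[str, int]:
    """Insert/update the batch; returns per-table written-row counts.

    ``upsert`` (default) replaces the row with the same natural key, making
    reloads idempotent; ``append`` inserts unconditionally, leaving natural
    key duplicates for the integrity check to flag.
    """
    if mode not in ("upsert", "append"):
        raise ValueError(f"unknown load mode {mode!r}")
    written: dict[str, int] = {}
    # primary tables first so child rows can resolve the parent key
    ordered = sorted(
        batch.tables.items(), key=lambda kv: bool(schema.tables[kv[0]].natural_key) is False
    )
    for table, rows in ordered:
        spec = schema.tables.get(table)
        if spec is None:
            raise StoreError(f"batch targets unknown table {table!r}")
        colnames = [c for c, _ in spec.columns]
        n = 0
        if not spec.natural_key:
            # child/detail table: replace this parent's rows wholesale
            parent_ids = {r.get("patient_logical_id") for r in rows}
            for pid in parent_ids:
                schema.conn.execute(
                    f'DELETE FROM "{table}" WHERE patient_logical_id = ?', (pid,)
                )
        for raw in rows:
            row = _translate_row(schema, raw)
            values = {c: row.get(c) for c in colnames}
            if spec.natural_key and mode == "upsert":
                key_col = spec.natural_key[0]
                existing = schema.conn.execute(
                    f'SELECT pk FROM "{table}" WHERE "{key_col}" = ?',
                    (values[key_col],),
                ).fetchone()
                if existing:
                    sets = ", ".join(f'"{c}" = ?' for c in colnames)
                    schema.conn.execute(
                        f'UPDATE "{table}" SET {sets} WHERE pk = ?',
                        [values[c] for c in colnames] + [existing[0]],
                    )
                    n += 1
                    continue
            placeholders = ", ".join("?" for _ in colnames)
            quoted = ", ".join(f'"{c}"' for c in colnames)
            schema.conn.execute(
                f'INSERT INTO "{table}" ({quoted}) VALUES ({placeholders})',
                [values[c] for c in colnames],
            )
            n += 1
        written[table] = written.get(table, 0) + n
    schema.conn.commit()
    return written


def resolve_references(schema: SchemaHandle) -> int:
    """Re-resolve every (key, ref-id) pair against the loaded natural keys.

    Makes load results independent of stream order; returns the number of
    still-unresolved (orphan) references.
    """
    unresolved = 0
    for spec in schema.tables.values():
        for key_col, id_col, target in spec.reference_pairs:
            schema.conn.execute(
                f'UPDATE "{spec.name}" SET "{key_col}" = '
                f'(SELECT pk FROM "{target}" WHERE "{target}".logical_id = '
                f'"{spec.name}"."{id_col}") WHERE "{id_col}" IS NOT NULL'
            )
            (n,) = schema.conn.execute(
                f'SELECT COUNT(*) FROM "{spec.name}" '
                f'WHERE "{id_col}" IS NOT NULL AND "{key_col}" IS NULL'
            ).fetchone()
            unresolved += n
    schema.conn.commit()
    return unresolved


def table_counts(schema: SchemaHandle) -> dict[str, int]:
    return {
        name: schema.conn.execute(f'SELECT COUNT(*) FROM "{name}"').fetchone()[0]
        for name in schema.tables
    }


def integrity_check(schema: SchemaHandle) -> IntegrityReport:
    """Enumerate orphan references, duplicate natural keys, and null rates."""
    report = IntegrityReport()
    for spec in schema.tables.values():
        for key_col, id_col, _target in spec.reference_pairs:
            rows = schema.conn.execute(
                f'SELECT "{id_col}" FROM "{spec.name}" '
                f'WHERE "{id_col}" IS NOT NULL AND "{key_col}" IS NULL'
            ).fetchall()
            report.orphans[f"{spec.name}.{key_col}"] = len(rows)
            for (ref_id,) in rows:
                report.orphan_rows.append((spec.name, key_col, str(ref_id)))
        if spec.natural_key:
            key_col = spec.natural_key[0]
            dups = schema.conn.execute(
                f'SELECT COUNT(*) FROM (SELECT "{key_col}" FROM "{spec.name}" '
                f'GROUP BY "{key_col}" HAVING COUNT(*) > 1)'
            ).fetchone()[0]
            report.duplicate_natural_keys[spec.name] = dups
    for table, column in _ANALYTIC_COLUMNS:
        total = schema.conn.execute(f'SELECT COUNT(*) FROM "{table}"').fetchone()[0]
        if total:
            nulls = schema.conn.execute(
                f'SELECT COUNT(*) FROM "{table}" WHERE "{column}" IS NULL'
            ).fetchone()[0]
            report.null_rates[f"{table}.{column}"] = nulls / total
    return report
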