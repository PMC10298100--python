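"""Template-driven flattening of FHIR JSON trees into relational rows.

Each resource type has a :class:`MappingTemplate`: an ordered list of
entries pairing a dotted element path (with ``[n]``/``[*]`` markers for
FHIR's repeated elements) with a target table and column.  Flattening walks
the template entries against the element tree with a counter-decrement
loop; absent elements map to null, repeated entries produce one child-table
row per occurrence, and reference entries store the parsed (type, id) pair
for key resolution at load time.

``drf_run`` ("data retrieval on the fly") streams resources from a source
through the templates straight into the relational store without
materializing the whole dataset, and is idempotent: rows are upserted by
the (resource type, logical id) natural key.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .errors import (
    MappingContractError,
    ReferenceParseError,
    RowMappingError,
    TemplateNotFoundError,
)
from .model import (
    ReferenceView,
    ResourceEnvelope,
    ResourceType,
    parse_reference,
    split_path,
    walk_path,
)

SCALAR = "scalar"
REPEATED = "repeated"

TRANSFORMS = ("identity", "date_normalize", "reference_to_key", "concat")


@dataclass(frozen=True)
class TemplateEntry:
    source_path: str
    target_table: str
    target_column: str
    cardinality: str = SCALAR
    transform: str = "identity"


@dataclass
class MappingTemplate:
    resource_type: ResourceType
    entries: list[TemplateEntry]

    def __post_init__(self) -> None:
        paths = [e.source_path for e in self.entries]
        if len(paths) != len(set(paths)):
            raise MappingContractError(
                f"duplicate source paths in {self.resource_type.value} template"
            )
        if not any(e.target_column == "logical_id" for e in self.entries):
            raise MappingContractError(
                f"{self.resource_type.value} template lacks a logical_id entry"
            )

    @property
    def primary_table(self) -> str:
        for e in self.entries:
            if e.target_column == "logical_id":
                return e.target_table
        raise MappingContractError("template lacks a logical_id entry")


def count_template_tags(template: MappingTemplate) -> int:
    """Number of template entries; the loop bound of the mapping main loop."""
    return len(template.entries)


@dataclass
class RowBatch:
    """Flattened relational rows produced from one resource."""

    tables: dict[str, list[dict[str, Any]]]
    provenance: tuple[ResourceType, str]


@dataclass
class MappingReport:
    resources_read: dict[ResourceType, int] = field(default_factory=dict)
    rows_written: dict[str, int] = field(default_factory=dict)
    skipped: list[tuple[str, str, str]] = field(default_factory=list)

    @property
    def total_read(self) -> int:
        return sum(self.resources_read.values())


# --------------------------------------------------------------------------
# Default template registry
#
# Reference columns are named `<role>_ref`; the store spreads each into a
# `<role>_key` surrogate-key column plus a `<role>_ref_id` natural-id column.


def _entries(table: str, specs: list[tuple]) -> list[TemplateEntry]:
    out = []
    for spec in specs:
        path, column = spec[0], spec[1]
        cardinality = spec[2] if len(spec) > 2 else SCALAR
        transform = spec[3] if len(spec) > 3 else "identity"
        out.append(TemplateEntry(path, table, column, cardinality, transform))
    return out


def build_default_registry() -> dict[ResourceType, MappingTemplate]:
    """Templates for all seven resource kinds.

    Patient spreads over a primary table plus telecom/address child tables;
    every other type maps to a single table.
    """
    registry: dict[ResourceType, MappingTemplate] = {}

    patient = _entries(
        "patient",
        [
            ("id", "logical_id"),
            ("identifier[0].value", "identifier"),
            ("name[0].family", "family"),
            ("name[0].given", "given", SCALAR, "concat"),
            ("gender", "gender"),
            ("birthDate", "birth_date", SCALAR, "date_normalize"),
            ("extension[0].valueDate", "registration_date", SCALAR, "date_normalize"),
        ],
    ) + _entries(
        "patient_telecom",
        [
            ("telecom[*].system", "system", REPEATED),
            ("telecom[*].value", "value", REPEATED),
        ],
    ) + _entries(
        "patient_address",
        [
            ("address[*].line[0]", "line", REPEATED),
            ("address[*].city", "city", REPEATED),
            ("address[*].country", "country", REPEATED),
        ],
    )
    registry[ResourceType.PATIENT] = MappingTemplate(ResourceType.PATIENT, patient)

    registry[ResourceType.ALLERGY_INTOLERANCE] = MappingTemplate(
        ResourceType.ALLERGY_INTOLERANCE,
        _entries(
            "allergy",
            [
                ("id", "logical_id"),
                ("identifier[0].value", "identifier"),
                ("clinicalStatus.coding[0].code", "clinical_status"),
                ("code.coding[0].display", "code_display"),
                ("patient.reference", "patient_ref", SCALAR, "reference_to_key"),
            ],
        ),
    )

    registry[ResourceType.CONDITION] = MappingTemplate(
        ResourceType.CONDITION,
        _entries(
            "condition",
            [
                ("id", "logical_id"),
                ("identifier[0].value", "identifier"),
                ("clinicalStatus.coding[0].code", "clinical_status"),
                ("category[0].coding[0].code", "category"),
                ("code.coding[0].display", "code_display"),
                ("subject.reference", "patient_ref", SCALAR, "reference_to_key"),
            ],
        ),
    )

    registry[ResourceType.PRACTITIONER] = MappingTemplate(
        ResourceType.PRACTITIONER,
        _entries(
            "practitioner",
            [
                ("id", "logical_id"),
                ("identifier[0].value", "identifier"),
                ("name[0].family", "family"),
                ("name[0].given", "given", SCALAR, "concat"),
                ("address[0].city", "city"),
                ("qualification[0].code.text", "qualification"),
            ],
        ),
    )

    registry[ResourceType.SERVICE_REQUEST] = MappingTemplate(
        ResourceType.SERVICE_REQUEST,
        _entries(
            "service_request",
            [
                ("id", "logical_id"),
                ("identifier[0].value", "identifier"),
                ("basedOn[0].reference", "based_on_ref", SCALAR, "reference_to_key"),
                ("status", "status"),
                ("category[0].coding[0].code", "category"),
                ("code.coding[0].display", "code_display"),
                ("authoredOn", "authored_on", SCALAR, "date_normalize"),
                ("subject.reference", "patient_ref", SCALAR, "reference_to_key"),
                ("requester.reference", "requester_ref", SCALAR, "reference_to_key"),
            ],
        ),
    )

    registry[ResourceType.DIAGNOSTIC_REPORT] = MappingTemplate(
        ResourceType.DIAGNOSTIC_REPORT,
        _entries(
            "diagnostic_report",
            [
                ("id", "logical_id"),
                ("identifier[0].value", "identifier"),
                ("basedOn[0].reference", "based_on_ref", SCALAR, "reference_to_key"),
                ("status", "status"),
                ("category[0].coding[0].code", "category"),
                ("code.coding[0].display", "code_display"),
                ("subject.reference", "patient_ref", SCALAR, "reference_to_key"),
            ],
        ),
    )

    registry[ResourceType.APPOINTMENT] = MappingTemplate(
        ResourceType.APPOINTMENT,
        _entries(
            "appointment",
            [
                ("id", "logical_id"),
                ("identifier[0].value", "identifier"),
                ("status", "status"),
                ("appointmentType.coding[0].code", "appointment_type"),
                ("priority", "priority"),
                (
                    "participant[0].actor.reference",
                    "patient_ref",
                    SCALAR,
                    "reference_to_key",
                ),
            ],
        ),
    )
    return registry


DEFAULT_REGISTRY = build_default_registry()


def resource_template(
    rtype: ResourceType | str,
    registry: dict[ResourceType, MappingTemplate] | None = None,
) -> MappingTemplate:
    """Look up the registered template for a resource type."""
    registry = registry if registry is not None else DEFAULT_REGISTRY
    try:
        rtype = ResourceType(rtype)
    except ValueError:
        raise TemplateNotFoundError(f"no template registered for {rtype!r}") from None
    if rtype not in registry:
        raise TemplateNotFoundError(f"no template registered for {rtype.value}")
    return registry[rtype]


# --------------------------------------------------------------------------
# Flattening


def _apply_transform(value: Any, transform: str) -> Any:
    if value is None:
        return None
    if transform in ("identity", "date_normalize"):
        # Dates are stored verbatim (ISO-8601, possibly partial); padding
        # happens only at analytics time.
        return value
    if transform == "concat":
        if isinstance(value, list):
            return " ".join(str(v) for v in value if v is not None)
        return str(value)
    if transform == "reference_to_key":
        return parse_reference(value)
    raise MappingContractError(f"unknown transform {transform!r}")


def _split_repeat(path: str) -> tuple[str, str]:
    """Split a repeated path at its ``[*]`` marker into (root, remainder)."""
    i = path.find("[*]")
    if i < 0:
        raise MappingContractError(f"repeated entry path {path!r} lacks a [*] marker")
    root = path[:i]
    rest = path[i + 3 :].lstrip(".")
    return root, rest


def map_resource(env: ResourceEnvelope, template: MappingTemplate) -> RowBatch:
    """Flatten one resource through its template into relational rows."""
    if env.resource_type != template.resource_type:
        raise MappingContractError(
            f"envelope type {env.resource_type.value} does not match template "
            f"type {template.resource_type.value}"
        )
    primary = template.primary_table
    primary_row: dict[str, Any] = {}
    repeated: dict[str, list[TemplateEntry]] = {}

    counter = count_template_tags(template)
    index = 0
    while counter > 0:  # counter-decrement loop over template entries
        entry = template.entries[index]
        if entry.cardinality == REPEATED:
            repeated.setdefault(entry.target_table, []).append(entry)
        else:
            value = walk_path(env.elements, entry.source_path)
            try:
                primary_row[entry.target_column] = _apply_transform(
                    value, entry.transform
                )
            except ReferenceParseError as exc:
                raise RowMappingError(
                    f"{entry.source_path}: {exc}",
                    resource_type=env.resource_type.value,
                    logical_id=env.logical_id,
                ) from exc
        index += 1
        counter -= 1

    tables: dict[str, list[dict[str, Any]]] = {primary: [primary_row]}
    parent_key_column = f"{primary}_logical_id"
    for table, entries in repeated.items():
        roots = {_split_repeat(e.source_path)[0] for e in entries}
        if len(roots) != 1:
            raise MappingContractError(
                f"child table {table!r} entries disagree on their repeat root"
            )
        root = roots.pop()
        occurrences = walk_path(env.elements, root)
        if occurrences is None:
            occurrences = []
        elif not isinstance(occurrences, list):
            occurrences = [occurrences]
        rows = []
        for occ in occurrences:
            row: dict[str, Any] = {parent_key_column: env.logical_id}
            for entry in entries:
                _, rest = _split_repeat(entry.source_path)
                sub = _walk_sub(occ, rest)
                row[entry.target_column] = _apply_transform(sub, entry.transform)
            rows.append(row)
        tables[table] = rows
    return RowBatch(tables=tables, provenance=(env.resource_type, env.logical_id))


def _walk_sub(node: Any, rest: str) -> Any:
    if not rest:
        return node
    from .model import _walk  # shared resolver

    return _walk(node, split_path(rest))


# --------------------------------------------------------------------------
# Registry (de)serialization — user-editable mappings without code changes.


def registry_to_dict(
    registry: dict[ResourceType, MappingTemplate]
) -> dict[str, list[dict[str, str]]]:
    return {
        rtype.value: [
            {
                "source_path": e.source_path,
                "target_table": e.target_table,
                "target_column": e.target_column,
                "cardinality": e.cardinality,
                "transform": e.transform,
            }
            for e in template.entries
        ]
        for rtype, template in registry.items()
    }


def registry_from_dict(data: dict[str, Any]) -> dict[ResourceType, MappingTemplate]:
    registry = {}
    for type_name, entries in data.items():
        rtype = ResourceType(type_name)
        registry[rtype] = MappingTemplate(
            rtype,
            [
                TemplateEntry(
                    source_path=e["source_path"],
                    target_table=e["target_table"],
                    target_column=e["target_column"],
                    cardinality=e.get("cardinality", SCALAR),
                    transform=e.get("transform", "identity"),
                )
                for e in entries
            ],
        )
    return registry


def load_registry(path: str | Path) -> dict[ResourceType, MappingTemplate]:
    data = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    return registry_from_dict(data)


def save_registry(
    registry: dict[ResourceType, MappingTemplate], path: str | Path
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(registry_to_dict(registry), fh, sort_keys=False)


# --------------------------------------------------------------------------
# DRF — stream source → templates → store


def drf_run(
    source,
    types: list[ResourceType],
    schema,
    registry: dict[ResourceType, MappingTemplate] | None = None,
    strict: bool = False,
) -> MappingReport:
    """Stream resources from a source through the templates into the store.

    Parents load before children in the given type order, and a final
    reference-resolution pass makes the result independent of stream order.
    Re-running on the same fixture is a no-op for table counts (upserts).
    """
    from .source import retrieve_resources  # late import to avoid a cycle
    from .store import load_rows, resolve_references

    report = MappingReport()
    for rtype in types:
        template = resource_template(rtype, registry)
        report.resources_read.setdefault(rtype, 0)
        for env in retrieve_resources(source, rtype, {}):
            report.resources_read[rtype] += 1
            try:
                batch = map_resource(env, template)
            except RowMappingError as exc:
                if strict:
                    raise
                report.skipped.append(
                    (env.resource_type.value, env.logical_id, str(exc))
                )
                continue
            written = load_rows(schema, batch)
            for table, n in written.items():
                report.rows_written[table] = report.rows_written.get(table, 0) + n
    resolve_references(schema)
    return report
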