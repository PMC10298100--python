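"""Typed in-memory representation of the seven FHIR R4 resource kinds.

A :class:`ResourceEnvelope` wraps one parsed resource: its type, its logical
id, and the full JSON element tree, stored losslessly so that mapping
templates — not the parser — decide which elements matter.  The module also
reads and writes the two bulk dialects used for FHIR interchange (NDJSON and
collection Bundles) and parses resource references, which are the join keys
of the relational mapping.

FHIR dates are kept verbatim as ISO-8601 strings; the standard permits
partial dates (``1950``, ``1950-06``), so year extraction is deferred to the
analytics layer.  All file I/O is UTF-8.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Any, Iterable, Iterator

from .errors import (
    CollectionReadError,
    ReferenceParseError,
    ResourceParseError,
    UnsupportedResourceError,
)


class ResourceType(str, Enum):
    """The seven FHIR R4 resource kinds handled by the pipeline."""

    PATIENT = "Patient"
    ALLERGY_INTOLERANCE = "AllergyIntolerance"
    PRACTITIONER = "Practitioner"
    CONDITION = "Condition"
    SERVICE_REQUEST = "ServiceRequest"
    DIAGNOSTIC_REPORT = "DiagnosticReport"
    APPOINTMENT = "Appointment"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


SUPPORTED_TYPES: tuple[ResourceType, ...] = tuple(ResourceType)


@dataclass(frozen=True)
class ResourceEnvelope:
    """One parsed FHIR resource.

    ``elements`` is the complete JSON tree (string-keyed dicts, lists for
    repeated elements, scalar leaves).  It is treated as immutable by
    convention: nothing in the pipeline mutates it after parsing.
    """

    resource_type: ResourceType
    logical_id: str
    elements: dict[str, Any]

    def get(self, path: str) -> Any:
        """Resolve a dotted element path (see :func:`walk_path`)."""
        return walk_path(self.elements, path)


@dataclass(frozen=True)
class ReferenceView:
    """A parsed FHIR reference: the (type, id) pair used as a join key."""

    target_type: ResourceType
    target_id: str


@dataclass(frozen=True)
class CodingView:
    """One coding from a CodeableConcept; carrier for allergy/test labels."""

    system: str
    code: str
    display: str


def first_coding(codeable: Any) -> CodingView | None:
    """Extract the first coding of a CodeableConcept dict, if any."""
    if not isinstance(codeable, dict):
        return None
    codings = codeable.get("coding")
    if not isinstance(codings, list) or not codings:
        return None
    c = codings[0]
    view = CodingView(
        system=str(c.get("system", "")),
        code=str(c.get("code", "")),
        display=str(c.get("display", "")),
    )
    if not view.code and not view.display:
        return None
    return view


# --------------------------------------------------------------------------
# Element-path addressing


_TOKEN_RE = re.compile(r"^([A-Za-z_][A-Za-z0-9_]*)(?:\[(\d+|\*)\])?$")


def split_path(path: str) -> list[tuple[str, str | None]]:
    """Tokenize a dotted path like ``name[0].given[0]`` into (name, index) pairs.

    The index is ``None`` (no marker), a decimal string, or ``"*"`` for
    "every occurrence".
    """
    tokens: list[tuple[str, str | None]] = []
    for part in path.split("."):
        m = _TOKEN_RE.match(part)
        if m is None:
            raise ValueError(f"bad path segment {part!r} in {path!r}")
        tokens.append((m.group(1), m.group(2)))
    return tokens


def walk_path(tree: Any, path: str) -> Any:
    """Resolve ``path`` against a JSON tree; absent elements yield ``None``.

    ``[n]`` selects one occurrence of a repeated element, ``[*]`` maps over
    all occurrences (returning a list).  A plain name on a repeated element
    returns the whole list.
    """
    return _walk(tree, split_path(path))


def _walk(node: Any, tokens: list[tuple[str, str | None]]) -> Any:
    if node is None:
        return None
    if not tokens:
        return node
    if not isinstance(node, dict):
        return None
    name, idx = tokens[0]
    rest = tokens[1:]
    val = node.get(name)
    if val is None:
        return None
    if idx is None:
        if isinstance(val, list):
            return [_walk(v, rest) for v in val] if rest else val
        return _walk(val, rest)
    if idx == "*":
        occurrences = val if isinstance(val, list) else [val]
        return [_walk(v, rest) for v in occurrences]
    i = int(idx)
    if isinstance(val, list):
        return _walk(val[i], rest) if i < len(val) else None
    return _walk(val, rest) if i == 0 else None


# --------------------------------------------------------------------------
# Parsing / serialization


def envelope_from_tree(tree: Any) -> ResourceEnvelope:
    """Build an envelope from an already-decoded JSON tree."""
    if not isinstance(tree, dict) or "resourceType" not in tree:
        raise UnsupportedResourceError("JSON object has no 'resourceType' member")
    type_name = tree["resourceType"]
    try:
        rtype = ResourceType(type_name)
    except ValueError:
        raise UnsupportedResourceError(
            f"resourceType {type_name!r} is outside the supported kinds "
            f"({', '.join(t.value for t in SUPPORTED_TYPES)})"
        ) from None
    logical_id = tree.get("id")
    if not logical_id or not isinstance(logical_id, str):
        raise ResourceParseError(
            f"{type_name} resource has no non-empty string 'id'"
        )
    return ResourceEnvelope(resource_type=rtype, logical_id=logical_id, elements=tree)


def parse_resource(raw_json_text: str) -> ResourceEnvelope:
    """Parse one FHIR resource from JSON text, losslessly.

    Unknown elements are preserved in the tree; only the seven supported
    resource kinds are accepted.
    """
    try:
        tree = json.loads(raw_json_text)
    except json.JSONDecodeError as exc:
        raise ResourceParseError(
            f"malformed JSON at byte offset {exc.pos}: {exc.msg}", offset=exc.pos
        ) from None
    return envelope_from_tree(tree)


def serialize_resource(env: ResourceEnvelope) -> str:
    """Emit the envelope as FHIR JSON; ``parse_resource`` inverts it exactly."""
    return json.dumps(env.elements, ensure_ascii=False)


# --------------------------------------------------------------------------
# Bulk collection reading


def read_resource_collection(
    location: str | Path,
    dialect: str = "ndjson",
    skip_malformed: bool = False,
    skipped: list[tuple[int, str]] | None = None,
) -> Iterator[ResourceEnvelope]:
    """Stream envelopes from an NDJSON file or a collection Bundle.

    Yields envelopes in file order.  A malformed line/entry raises
    :class:`CollectionReadError` naming its index unless ``skip_malformed``
    is set, in which case the index and reason are appended to ``skipped``.
    """
    path = Path(location)
    if dialect == "ndjson":
        yield from _read_ndjson(path, skip_malformed, skipped)
    elif dialect == "bundle":
        yield from _read_bundle(path, skip_malformed, skipped)
    else:
        raise ValueError(f"unknown collection dialect {dialect!r}")


def _read_ndjson(path, skip_malformed, skipped):
    with open(path, encoding="utf-8") as fh:
        for index, line in enumerate(fh):
            if not line.strip():
                continue
            try:
                yield parse_resource(line)
            except (ResourceParseError, UnsupportedResourceError) as exc:
                if skip_malformed:
                    if skipped is not None:
                        skipped.append((index, str(exc)))
                    continue
                raise CollectionReadError(
                    f"line {index}: {exc}", index=index
                ) from exc


def _read_bundle(path, skip_malformed, skipped):
    with open(path, encoding="utf-8") as fh:
        bundle = json.load(fh)
    entries = bundle.get("entry", []) if isinstance(bundle, dict) else []
    for index, entry in enumerate(entries):
        try:
            resource = entry.get("resource") if isinstance(entry, dict) else None
            if resource is None:
                raise UnsupportedResourceError("entry has no 'resource'")
            yield envelope_from_tree(resource)
        except (ResourceParseError, UnsupportedResourceError) as exc:
            if skip_malformed:
                if skipped is not None:
                    skipped.append((index, str(exc)))
                continue
            raise CollectionReadError(f"entry {index}: {exc}", index=index) from exc


def write_resource_collection(
    envelopes: Iterable[ResourceEnvelope], path: str | Path
) -> int:
    """Write envelopes as NDJSON (one resource per line); returns the count."""
    n = 0
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for env in envelopes:
            fh.write(serialize_resource(env))
            fh.write("\n")
            n += 1
    return n


# --------------------------------------------------------------------------
# References

# "Type/id" at the end of the string, optionally preceded by an absolute URL.
_REF_RE = re.compile(r"(?:^|/)([A-Za-z]+)/([A-Za-z0-9._-]{1,64})$")


def parse_reference(ref: str) -> ReferenceView:
    """Parse ``"Patient/23"`` or ``"http://host/fhir/Patient/23"`` to a view.

    Bare ids are rejected: FHIR relative references are typed, and an
    untyped id would be an ambiguous join key.
    """
    if not ref or not isinstance(ref, str):
        raise ReferenceParseError(str(ref))
    m = _REF_RE.search(ref.strip())
    if m is None:
        raise ReferenceParseError(ref)
    type_name, target_id = m.group(1), m.group(2)
    try:
        rtype = ResourceType(type_name)
    except ValueError:
        raise ReferenceParseError(ref) from None
    return ReferenceView(target_type=rtype, target_id=target_id)
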