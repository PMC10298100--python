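"""Uniform bulk retrieval over a local fixture store or a FHIR REST endpoint.

The query engine gathers resources in bulk: an empty parameter map means
"retrieve all of the type", and a small fixed set of search parameters
(`identifier`, `given`, `birthDate`, `_id`) filters with exact string
matching (date-prefix matching for `birthDate`).  REST retrieval pages
through searchset Bundles following `next` links; local retrieval filters
the per-type NDJSON (or Bundle) files client-side, so both sources yield
the same multiset of envelopes for the same dataset.
"""

from __future__ import annotations

import json
import time
import urllib.error
import urllib.parse
import urllib.request
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterator

from .errors import SourceError, TransportError, UnsupportedParameterError
from .model import (
    ResourceEnvelope,
    ResourceType,
    envelope_from_tree,
    read_resource_collection,
    walk_path,
)

LOCAL_STORE = "local_store"
REST_ENDPOINT = "rest_endpoint"

MAX_RETRIES = 3
RETRY_BACKOFF_SECONDS = 0.2  # doubled on each retry; idempotent GETs only

SearchParams = dict[str, str]


@dataclass
class ResourceSource:
    kind: str  # local_store | rest_endpoint
    base: str  # directory path or REST base URL
    page_size: int = 50  # rest only


@dataclass
class RetrievalReport:
    """Per-type envelope counts from a bulk retrieval run."""

    counts: dict[ResourceType, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def open_source(uri: str, page_size: int = 50) -> ResourceSource:
    """Infer the source kind from the URI scheme and check readability."""
    if uri.startswith(("http://", "https://")):
        return ResourceSource(kind=REST_ENDPOINT, base=uri.rstrip("/"), page_size=page_size)
    if "://" in uri:
        scheme = uri.split("://", 1)[0]
        raise SourceError(f"unsupported source scheme {scheme!r}")
    path = Path(uri)
    if not path.is_dir():
        raise SourceError(f"source directory {uri!r} does not exist")
    has_files = any(path.glob("*.ndjson")) or any(path.glob("*.json"))
    if not has_files:
        raise SourceError(
            f"source directory {uri!r} holds no .ndjson or Bundle .json files"
        )
    return ResourceSource(kind=LOCAL_STORE, base=str(path))


# --------------------------------------------------------------------------
# Search-parameter matching (shared by local filtering)

def _match_id(env: ResourceEnvelope, value: str) -> bool:
    return env.logical_id == value


def _match_identifier(env: ResourceEnvelope, value: str) -> bool:
    values = walk_path(env.elements, "identifier[*].value") or []
    return value in [str(v) for v in values if v is not None]


def _match_given(env: ResourceEnvelope, value: str) -> bool:
    names = walk_path(env.elements, "name[*].given") or []
    for given_list in names:
        if isinstance(given_list, list) and value in given_list:
            return True
    return False


def _match_birth_date(env: ResourceEnvelope, value: str) -> bool:
    bd = walk_path(env.elements, "birthDate")
    return isinstance(bd, str) and bd.startswith(value)


_MATCHERS: dict[str, Callable[[ResourceEnvelope, str], bool]] = {
    "_id": _match_id,
    "identifier": _match_identifier,
    "given": _match_given,
    "birthDate": _match_birth_date,
}


def matches(env: ResourceEnvelope, params: SearchParams) -> bool:
    """True when the envelope satisfies every search parameter."""
    for name, value in params.items():
        matcher = _MATCHERS.get(name)
        if matcher is None:
            raise UnsupportedParameterError(f"unsupported search parameter {name!r}")
        if not matcher(env, value):
            return False
    return True


def _check_params(params: SearchParams) -> None:
    for name in params:
        if name not in _MATCHERS:
            raise UnsupportedParameterError(f"unsupported search parameter {name!r}")


# --------------------------------------------------------------------------
# Retrieval


def retrieve_resources(
    source: ResourceSource,
    rtype: ResourceType,
    params: SearchParams | None = None,
) -> Iterator[ResourceEnvelope]:
    """Yield every resource of ``rtype`` matching all ``params``."""
    params = dict(params or {})
    _check_params(params)
    if source.kind == LOCAL_STORE:
        yield from _retrieve_local(source, rtype, params)
    elif source.kind == REST_ENDPOINT:
        yield from _retrieve_rest(source, rtype, params)
    else:  # pragma: no cover - constructor prevents this
        raise SourceError(f"unknown source kind {source.kind!r}")


def _retrieve_local(source, rtype, params):
    base = Path(source.base)
    ndjson = base / f"{rtype.value}.ndjson"
    bundle = base / f"{rtype.value}.json"
    if ndjson.exists():
        stream = read_resource_collection(ndjson, dialect="ndjson")
    elif bundle.exists():
        stream = read_resource_collection(bundle, dialect="bundle")
    else:
        return
    for env in stream:
        if matches(env, params):
            yield env


def _get_json(url: str) -> dict:
    """GET a JSON document with bounded retries and exponential backoff."""
    last_status: int | None = None
    last_error: Exception | None = None
    delay = RETRY_BACKOFF_SECONDS
    for attempt in range(MAX_RETRIES):
        try:
            with urllib.request.urlopen(url) as response:
                return json.loads(response.read().decode("utf-8"))
        except urllib.error.HTTPError as exc:
            last_status, last_error = exc.code, exc
            if 400 <= exc.code < 500:  # not retryable
                break
        except (urllib.error.URLError, OSError, json.JSONDecodeError) as exc:
            last_error = exc
        if attempt < MAX_RETRIES - 1:
            time.sleep(delay)
            delay *= 2
    raise TransportError(
        f"GET {url} failed after {MAX_RETRIES} attempts: {last_error}",
        status=last_status,
    )


def _retrieve_rest(source, rtype, params):
    query = dict(params)
    query["_count"] = str(source.page_size)
    url = f"{source.base}/{rtype.value}?{urllib.parse.urlencode(query)}"
    while url:
        bundle = _get_json(url)
        for entry in bundle.get("entry", []):
            resource = entry.get("resource")
            if resource is not None:
                yield envelope_from_tree(resource)
        url = _next_link(bundle)


def _next_link(bundle: dict) -> str | None:
    for link in bundle.get("link", []):
        if link.get("relation") == "next":
            return link.get("url")
    return None


def retrieve_all(
    source: ResourceSource, types: list[ResourceType]
) -> tuple[dict[ResourceType, list[ResourceEnvelope]], RetrievalReport]:
    """Retrieve every resource of each listed type; report counts per type."""
    if not types:
        raise ValueError("types must be non-empty")
    streams: dict[ResourceType, list[ResourceEnvelope]] = {}
    report = RetrievalReport()
    for rtype in types:
        try:
            envelopes = list(retrieve_resources(source, rtype, {}))
        except TransportError as exc:
            raise TransportError(
                f"retrieving {rtype.value}: {exc}", status=exc.status
            ) from exc
        streams[rtype] = envelopes
        report.counts[rtype] = len(envelopes)
    return streams, report
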