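"""Exception hierarchy shared across the pipeline."""


class FhirTabError(Exception):
    """Base class for all fhirtab errors."""


class ResourceParseError(FhirTabError):
    """Raised for syntactically malformed resource JSON; carries the byte offset."""

    def __init__(self, message: str, offset: int | None = None):
        super().__init__(message)
        self.offset = offset


class UnsupportedResourceError(FhirTabError):
    """The JSON names a resourceType outside the seven supported kinds (or none)."""


class ReferenceParseError(FhirTabError):
    """A FHIR reference string could not be resolved to (type, id)."""

    def __init__(self, raw: str):
        super().__init__(f"unparseable FHIR reference: {raw!r}")
        self.raw = raw


class CollectionReadError(FhirTabError):
    """A malformed NDJSON line or Bundle entry; carries the zero-based index."""

    def __init__(self, message: str, index: int):
        super().__init__(message)
        self.index = index


class SourceError(FhirTabError):
    """The retrieval source is absent, unreadable, or uses an unsupported scheme."""


class UnsupportedParameterError(FhirTabError):
    """A search parameter name outside the supported set."""


class TransportError(FhirTabError):
    """REST retrieval failed after the bounded retries; carries the last HTTP status."""

    def __init__(self, message: str, status: int | None = None):
        super().__init__(message)
        self.status = status


class TemplateNotFoundError(FhirTabError):
    """No mapping template is registered for the requested resource type."""


class MappingContractError(FhirTabError):
    """Envelope/template resource-type mismatch or a malformed template."""


class RowMappingError(FhirTabError):
    """One resource could not be flattened (e.g. a bad reference); skippable."""

    def __init__(self, message: str, resource_type: str = "", logical_id: str = ""):
        super().__init__(message)
        self.resource_type = resource_type
        self.logical_id = logical_id


class ConfigValidationError(FhirTabError):
    """Fixture configuration violates its invariants; carries the violation list."""

    def __init__(self, violations: list[str]):
        super().__init__("invalid fixture config: " + "; ".join(violations))
        self.violations = violations


class MigrationRequiredError(FhirTabError):
    """The store already holds an incompatible table layout."""


class StoreError(FhirTabError):
    """Generic relational-store failure."""
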