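"""Exception hierarchy shared across the store, registry, renderer and API."""

from __future__ import annotations


class LinkstoreError(Exception):
    """Base class for all package errors."""


class UnknownType(LinkstoreError):
    """Item type is not registered in the schema registry."""


class NotFound(LinkstoreError):
    """No document matches the given identifier."""


class UnresolvableToken(NotFound):
    """Identifier token matches neither a uuid nor any unique key."""


class ValidationFailure(LinkstoreError):
    """Properties do not conform to the item type's schema.

    ``violations`` is a list of ``{"name": <property>, "description": <text>}``
    mappings suitable for a 422 response body.
    """

    def __init__(self, violations):
        self.violations = list(violations)
        super().__init__("; ".join(v["description"] for v in self.violations))


class DuplicateKey(LinkstoreError):
    """A (key_name, key_value) pair is already registered to another uuid."""


class DanglingLink(LinkstoreError):
    """A link-valued property does not resolve to an existing document of the
    declared target type."""


class PermissionDenied(LinkstoreError):
    """The acting principal may not perform this operation."""


class UnknownFrame(LinkstoreError):
    """Frame name is not one of raw | object | embedded | page."""


class MissingUpgradeStep(LinkstoreError):
    """The upgrade chain for a type has a gap."""


class HookFailure(LinkstoreError):
    """A calculated-property hook raised; carries the field name."""

    def __init__(self, field, cause):
        self.field = field
        self.cause = cause
        super().__init__(f"calculated property {field!r} failed: {cause}")


class UnknownRevDeclaration(LinkstoreError):
    """(child type, child link field) is not declared by any rev field."""


class UnknownSyntax(LinkstoreError):
    """Requested RDF serialization syntax is not supported."""


class InvalidConfig(LinkstoreError):
    """Fixture generator configuration is not usable."""
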