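"""Schema registry: per-type JSON schemas with link/rev/calculated extensions,
document validation against a deliberately small JSON-Schema subset, and the
versioned upgrade chain applied on the read path.

Custom keywords understood on top of the core vocabulary:

``linkTo``
    On a property (or its ``items``): the target item type of a link.
``rev``
    Top-level mapping of calculated name -> {"type": child type,
    "field": child link field} declaring reverse links.
``calculatedProperty``
    Marks a property as computed at render time; rejected on write.
``facets``
    Ordered mapping of property path -> {"title": ...} driving search
    aggregations.
``schema_version``
    Current version of the schema (positive integer).
``uniqueKey``
    Registers the property as a unique key. The string value ``"accession"``
    (or ``"alias"``) names a global key; ``true`` scopes the key to the item
    type (key name ``"<type>:<property>"``).
``collection``
    URL collection name for the type (e.g. ``"biosamples"``).
``accessionCode``
    Two-letter code used when the server mints accessions.
``serverDefault`` / ``default``
    Value supplied by the server when the property is absent on create.
"""

from __future__ import annotations

import copy
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Callable

from .errors import MissingUpgradeStep, UnknownType, ValidationFailure

_FORMATS = {
    "date": re.compile(r"^\d{4}-\d{2}-\d{2}$"),
    "accession": re.compile(r"^TST[A-Z]{2}\d{3}[A-Z]{3}$"),
    "email": re.compile(r"^[^@\s]+@[^@\s]+\.[^@\s]+$"),
    "uuid": re.compile(
        r"^[0-9a-f]{8}-[0-9a-f]{4}-[0-9a-f]{4}-[0-9a-f]{4}-[0-9a-f]{12}$"
    ),
}

_TYPE_CHECKS = {
    "string": lambda v: isinstance(v, str),
    "number": lambda v: isinstance(v, (int, float)) and not isinstance(v, bool),
    "integer": lambda v: isinstance(v, int) and not isinstance(v, bool),
    "boolean": lambda v: isinstance(v, bool),
    "array": lambda v: isinstance(v, list),
    "object": lambda v: isinstance(v, dict),
    "null": lambda v: v is None,
}


def _violation(name: str, description: str) -> dict:
    return {"name": name, "description": description}


@dataclass
class ItemSchema:
    """One item type's parsed schema plus extension metadata."""

    item_type: str
    raw: dict
    version: int = 1

    def __post_init__(self):
        props = self.raw.get("properties", {})
        self.properties_spec: dict = props
        self.required: list = list(self.raw.get("required", []))
        self.version = int(self.raw.get("schema_version", self.version))
        self.collection: str = self.raw.get("collection", self.item_type + "s")
        self.title: str = self.raw.get("title", self.item_type.title())
        self.facet_config: dict = dict(self.raw.get("facets", {}))
        self.rev_fields: dict = {
            name: (decl["type"], decl["field"])
            for name, decl in self.raw.get("rev", {}).items()
        }
        self.link_fields: dict = {}
        self.calculated_marked: set = set()
        self.unique_keys: dict = {}
        self.accession_code: str | None = None
        for name, spec in props.items():
            if not isinstance(spec, dict):
                continue
            target = spec.get("linkTo") or (
                isinstance(spec.get("items"), dict)
                and spec["items"].get("linkTo")
            )
            if target:
                self.link_fields[name] = target
            if spec.get("calculatedProperty"):
                self.calculated_marked.add(name)
            uk = spec.get("uniqueKey")
            if uk:
                self.unique_keys[name] = (
                    uk if isinstance(uk, str) else f"{self.item_type}:{name}"
                )
            if spec.get("accessionType"):
                self.accession_code = spec["accessionType"]

    @property
    def name_key(self) -> str | None:
        """The property minting the canonical path: accession if declared,
        else the first other unique key."""
        if "accession" in self.unique_keys:
            return "accession"
        for name in self.unique_keys:
            return name
        return None

    def is_list_link(self, name: str) -> bool:
        spec = self.properties_spec.get(name, {})
        return spec.get("type") == "array"

    def extract_keys(self, properties: dict) -> list[tuple[str, str]]:
        """(key_name, key_value) pairs registered for these properties,
        including every element of list-valued keys (aliases)."""
        out = []
        for prop, key_name in sorted(self.unique_keys.items()):
            value = properties.get(prop)
            if value is None:
                continue
            values = value if isinstance(value, list) else [value]
            out.extend((key_name, str(v)) for v in values)
        return out


class SchemaRegistry:
    """Loads one JSON-Schema file per item type and serves validation,
    upgrades and /profiles/ content."""

    def __init__(self, schema_dir: str | Path | None = None):
        self._schemas: dict[str, ItemSchema] = {}
        self._by_collection: dict[str, str] = {}
        self._upgrade_steps: dict[tuple[str, int], Callable] = {}
        if schema_dir is not None:
            self.load_directory(schema_dir)

    # -- loading ---------------------------------------------------------

    def load_directory(self, schema_dir: str | Path) -> None:
        for path in sorted(Path(schema_dir).glob("*.json")):
            self.register_schema(path.stem, json.loads(path.read_text()))

    def register_schema(self, item_type: str, raw: dict) -> ItemSchema:
        schema = ItemSchema(item_type, raw)
        self._schemas[item_type] = schema
        self._by_collection[schema.collection] = item_type
        return schema

    def __contains__(self, item_type: str) -> bool:
        return item_type in self._schemas

    def __getitem__(self, item_type: str) -> ItemSchema:
        try:
            return self._schemas[item_type]
        except KeyError:
            raise UnknownType(item_type) from None

    @property
    def types(self) -> list[str]:
        return sorted(self._schemas)

    def type_for_collection(self, collection: str) -> str | None:
        return self._by_collection.get(collection)

    # -- profiles --------------------------------------------------------

    def profiles(self, item_type: str | None = None) -> dict:
        if item_type is not None:
            return copy.deepcopy(self[item_type].raw)
        return {t: copy.deepcopy(s.raw) for t, s in sorted(self._schemas.items())}

    # -- validation ------------------------------------------------------

    def validate(self, item_type: str, properties: dict) -> list[dict]:
        """Violations for ``properties`` against the current schema.

        Empty list iff the document conforms: no properties outside the
        schema, all present values conformant, all required present.
        """
        schema = self[item_type]
        violations: list[dict] = []
        if not isinstance(properties, dict):
            return [_violation("", "document body must be a JSON object")]
        for name, value in properties.items():
            spec = schema.properties_spec.get(name)
            if spec is None:
                violations.append(
                    _violation(name, f"property {name!r} is not allowed by the "
                                     f"{item_type} schema")
                )
                continue
            if name in schema.calculated_marked:
                violations.append(
                    _violation(name, f"property {name!r} is calculated and "
                                     f"read-only")
                )
                continue
            violations.extend(_check_value(name, value, spec))
        for name in schema.required:
            if name not in properties:
                violations.append(
                    _violation(name, f"required property {name!r} is missing")
                )
        return violations

    # -- upgrades --------------------------------------------------------

    def upgrade_step(self, item_type: str, from_version: int):
        """Decorator registering a pure ``properties -> properties`` transform
        lifting ``item_type`` documents from ``from_version`` to the next."""

        def register(fn):
            self._upgrade_steps[(item_type, int(from_version))] = fn
            return fn

        return register

    def upgrade_properties(
        self, item_type: str, properties: dict, schema_version: int | None
    ) -> tuple[dict, int]:
        """Apply the chain of upgrade steps up to the current version.

        Returns the (possibly copied) upgraded properties and the current
        version. Documents with no recorded version are treated as version 1.
        """
        schema = self[item_type]
        version = int(schema_version or 1)
        if version > schema.version:
            raise MissingUpgradeStep(
                f"{item_type} document at version {version} is newer than the "
                f"registered schema (version {schema.version})"
            )
        if version == schema.version:
            return properties, version
        properties = copy.deepcopy(properties)
        while version < schema.version:
            step = self._upgrade_steps.get((item_type, version))
            if step is None:
                raise MissingUpgradeStep(
                    f"no upgrade step for {item_type} from version {version}"
                )
            properties = step(properties)
            version += 1
        violations = self.validate(item_type, properties)
        if violations:
            raise ValidationFailure(
                [_violation(v["name"], "post-upgrade: " + v["description"])
                 for v in violations]
            )
        return properties, version


def _check_value(name: str, value: Any, spec: dict) -> list[dict]:
    """Core-vocabulary checks: type, enum, pattern, format, items."""
    out: list[dict] = []
    declared = spec.get("type")
    if declared is not None:
        types = declared if isinstance(declared, list) else [declared]
        if not any(_TYPE_CHECKS.get(t, lambda v: True)(value) for t in types):
            out.append(
                _violation(name, f"property {name!r} must be of type "
                                 f"{declared}, got {type(value).__name__}")
            )
            return out
    if "enum" in spec and value not in spec["enum"]:
        out.append(
            _violation(name, f"property {name!r} value {value!r} is not one "
                             f"of {spec['enum']}")
        )
    if "pattern" in spec and isinstance(value, str):
        if not re.search(spec["pattern"], value):
            out.append(
                _violation(name, f"property {name!r} value {value!r} does not "
                                 f"match pattern {spec['pattern']!r}")
            )
    fmt = spec.get("format")
    if fmt in _FORMATS and isinstance(value, str):
        if not _FORMATS[fmt].match(value):
            out.append(
                _violation(name, f"property {name!r} value {value!r} is not a "
                                 f"valid {fmt}")
            )
    if isinstance(value, list) and isinstance(spec.get("items"), dict):
        for i, element in enumerate(value):
            out.extend(_check_value(f"{name}[{i}]", element, spec["items"]))
    if isinstance(value, dict) and isinstance(spec.get("properties"), dict):
        sub = spec["properties"]
        for key, element in value.items():
            if key not in sub:
                out.append(
                    _violation(f"{name}.{key}",
                               f"property {name}.{key!r} is not allowed")
                )
            else:
                out.extend(_check_value(f"{name}.{key}", element, sub[key]))
    return out
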