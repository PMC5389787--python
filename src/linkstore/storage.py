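"""Transactional storage of typed JSON documents.

One sqlite row per document holds the JSON body; side tables hold the unique
key aliases and the write-ahead transaction log consumed by the indexer. All
writes are atomic: a rejected write leaves the store byte-identical.

Link-valued properties are normalized to target uuids at write time, after
referential-integrity resolution. Whenever a write adds, removes or retargets
a link, the old and new targets join the transaction's ``updated_uuids`` so
that reverse-link parents are invalidated even for brand-new children.
"""

from __future__ import annotations

import datetime
import json
import sqlite3
import uuid as uuidlib
from dataclasses import dataclass, field

from .errors import (
    DanglingLink,
    DuplicateKey,
    NotFound,
    PermissionDenied,
    UnresolvableToken,
    ValidationFailure,
)
from .schemas import SchemaRegistry

_ALPHABET = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"


def _letters3(n: int) -> str:
    a, b = divmod(n, 26)
    c, b = divmod(a, 26)
    return _ALPHABET[c % 26] + _ALPHABET[b] + _ALPHABET[n % 26]


@dataclass(frozen=True)
class Document:
    """One stored metadata object (links held as target uuids)."""

    uuid: str
    item_type: str
    schema_version: int
    properties: dict

    @property
    def status(self) -> str:
        return self.properties.get("status", "in progress")


@dataclass(frozen=True)
class TransactionRecord:
    """One write transaction, in log order."""

    tid: int
    updated_uuids: frozenset
    renamed_uuids: frozenset
    timestamp: str
    operations: tuple = field(default_factory=tuple)


class DocumentStore:
    """sqlite-backed document store with unique-key aliasing and a
    transaction log.

    ``acl`` is an optional callback ``(principal, action, item_type,
    document_properties) -> None`` raising :class:`PermissionDenied`; the REST
    layer installs the four-tier model here.
    """

    def __init__(self, registry: SchemaRegistry, path: str = ":memory:",
                 acl=None):
        self.registry = registry
        self.acl = acl
        # single-writer desk scale: requests are serialized by the service,
        # so cross-thread use of one connection is safe
        self.conn = sqlite3.connect(path, check_same_thread=False)
        self.conn.execute("PRAGMA foreign_keys = ON")
        self._create_tables()

    def _create_tables(self):
        with self.conn:
            self.conn.executescript(
                """
                CREATE TABLE IF NOT EXISTS documents (
                    uuid TEXT PRIMARY KEY,
                    item_type TEXT NOT NULL,
                    schema_version INTEGER NOT NULL,
                    properties TEXT NOT NULL
                );
                CREATE TABLE IF NOT EXISTS keys (
                    key_name TEXT NOT NULL,
                    key_value TEXT NOT NULL,
                    uuid TEXT NOT NULL,
                    PRIMARY KEY (key_name, key_value)
                );
                CREATE TABLE IF NOT EXISTS log (
                    tid INTEGER PRIMARY KEY AUTOINCREMENT,
                    updated TEXT NOT NULL,
                    renamed TEXT NOT NULL,
                    timestamp TEXT NOT NULL,
                    operations TEXT NOT NULL
                );
                """
            )

    # ------------------------------------------------------------------
    # identifier resolution

    def resolve_identifier(self, token: str) -> tuple[str, str]:
        """Resolve a uuid literal, unique key, or canonical path to
        ``(item_type, uuid)``."""
        if token.startswith("/") and token.count("/") >= 2:
            token = token.rstrip("/").rsplit("/", 1)[-1]
        row = self.conn.execute(
            "SELECT item_type FROM documents WHERE uuid = ?", (token,)
        ).fetchone()
        if row:
            return row[0], token
        row = self.conn.execute(
            "SELECT uuid FROM keys WHERE key_value = ? ORDER BY key_name LIMIT 1",
            (token,),
        ).fetchone()
        if row:
            return self.resolve_identifier(row[0])
        raise UnresolvableToken(token)

    def exists(self, token: str) -> bool:
        try:
            self.resolve_identifier(token)
            return True
        except UnresolvableToken:
            return False

    # ------------------------------------------------------------------
    # reads

    def get_item(self, identifier: str) -> Document:
        """Fetch by uuid or unique key; pending schema upgrades are applied
        on the way out without modifying the stored copy."""
        _, uid = self.resolve_identifier(identifier)
        row = self.conn.execute(
            "SELECT item_type, schema_version, properties FROM documents "
            "WHERE uuid = ?", (uid,)
        ).fetchone()
        if row is None:  # pragma: no cover - resolve already guarantees
            raise NotFound(identifier)
        item_type, version, props = row[0], row[1], json.loads(row[2])
        props, version = self.registry.upgrade_properties(
            item_type, props, version
        )
        return Document(uid, item_type, version, props)

    def items_of_type(self, item_type: str) -> list[Document]:
        rows = self.conn.execute(
            "SELECT uuid FROM documents WHERE item_type = ? ORDER BY uuid",
            (item_type,),
        ).fetchall()
        return [self.get_item(r[0]) for r in rows]

    def all_uuids(self) -> list[str]:
        return [r[0] for r in self.conn.execute(
            "SELECT uuid FROM documents ORDER BY uuid").fetchall()]

    def canonical_path(self, document: Document) -> str:
        """``/<collection>/<accession-or-name-or-uuid>/``"""
        schema = self.registry[document.item_type]
        name = document.uuid
        if schema.name_key:
            value = document.properties.get(schema.name_key)
            if value:
                name = value
        return f"/{schema.collection}/{name}/"

    # ------------------------------------------------------------------
    # writes

    def create_item(self, item_type: str, properties: dict,
                    principal=None) -> Document:
        schema = self.registry[item_type]
        if self.acl is not None:
            self.acl(principal, "create", item_type, properties)
        props = dict(properties)
        uid = props.pop("uuid", None)
        if uid is None:
            uid = str(uuidlib.uuid4())
        else:
            uid = str(uid)
            if self._uuid_exists(uid):
                raise DuplicateKey(f"uuid {uid} already exists")
        props = self._apply_server_defaults(schema, props)
        violations = self.registry.validate(item_type, props)
        if violations:
            raise ValidationFailure(violations)
        props, link_targets = self._resolve_links(schema, props)
        keys = schema.extract_keys(props)
        replay = dict(props)
        replay["uuid"] = uid
        try:
            with self.conn:
                self.conn.execute(
                    "INSERT INTO documents VALUES (?, ?, ?, ?)",
                    (uid, item_type, schema.version,
                     json.dumps(props, sort_keys=True)),
                )
                self._register_keys(keys, uid)
                self._append_log(
                    updated={uid} | link_targets,
                    renamed=set(),
                    operations=[{"op": "create", "item_type": item_type,
                                 "properties": replay}],
                )
        except sqlite3.IntegrityError as exc:
            raise DuplicateKey(str(exc)) from exc
        return Document(uid, item_type, schema.version, props)

    def update_item(self, identifier: str, delta: dict, mode: str = "patch",
                    principal=None) -> Document:
        if mode not in ("patch", "replace"):
            raise ValueError(f"unknown update mode {mode!r}")
        current = self.get_item(identifier)
        schema = self.registry[current.item_type]
        if self.acl is not None:
            self.acl(principal, "edit", current.item_type, current.properties)
        delta = dict(delta)
        delta.pop("uuid", None)  # uuid is immutable
        if mode == "patch":
            props = dict(current.properties)
            props.update(delta)
        else:
            props = dict(delta)
            # replacement never clears identity/lifecycle server fields
            for keep in ("accession", "status"):
                if keep in current.properties and keep not in props:
                    props[keep] = current.properties[keep]
            props = self._apply_server_defaults(schema, props)
        violations = self.registry.validate(current.item_type, props)
        if violations:
            raise ValidationFailure(violations)
        props, new_targets = self._resolve_links(schema, props)
        _, old_targets = self._resolve_links(schema, current.properties)
        link_delta = new_targets ^ old_targets
        renamed = set()
        if schema.name_key:
            old_name = current.properties.get(schema.name_key)
            new_name = props.get(schema.name_key)
            if old_name != new_name:
                renamed.add(current.uuid)
        new_keys = schema.extract_keys(props)
        old_keys = schema.extract_keys(current.properties)
        try:
            with self.conn:
                self.conn.execute(
                    "UPDATE documents SET schema_version = ?, properties = ? "
                    "WHERE uuid = ?",
                    (schema.version, json.dumps(props, sort_keys=True),
                     current.uuid),
                )
                if new_keys != old_keys:
                    for key_name, key_value in old_keys:
                        self.conn.execute(
                            "DELETE FROM keys WHERE key_name = ? AND "
                            "key_value = ? AND uuid = ?",
                            (key_name, key_value, current.uuid),
                        )
                    self._register_keys(new_keys, current.uuid)
                self._append_log(
                    updated={current.uuid} | link_delta,
                    renamed=renamed,
                    operations=[{"op": "update", "identifier": current.uuid,
                                 "delta": props if mode == "replace" else delta,
                                 "mode": mode}],
                )
        except sqlite3.IntegrityError as exc:
            raise DuplicateKey(str(exc)) from exc
        return Document(current.uuid, current.item_type, schema.version, props)

    # ------------------------------------------------------------------
    # transaction log

    def transactions_since(self, tid: int) -> list[TransactionRecord]:
        rows = self.conn.execute(
            "SELECT tid, updated, renamed, timestamp, operations FROM log "
            "WHERE tid > ? ORDER BY tid", (tid,)
        ).fetchall()
        return [
            TransactionRecord(
                tid=r[0],
                updated_uuids=frozenset(json.loads(r[1])),
                renamed_uuids=frozenset(json.loads(r[2])),
                timestamp=r[3],
                operations=tuple(json.loads(r[4])),
            )
            for r in rows
        ]

    def head_tid(self) -> int:
        row = self.conn.execute("SELECT MAX(tid) FROM log").fetchone()
        return row[0] or 0

    # ------------------------------------------------------------------
    # diagnostics / replay

    def dump(self) -> dict:
        """Canonical JSON-able snapshot of every table (atomicity oracle)."""
        docs = {
            r[0]: {"item_type": r[1], "schema_version": r[2],
                   "properties": json.loads(r[3])}
            for r in self.conn.execute(
                "SELECT uuid, item_type, schema_version, properties "
                "FROM documents ORDER BY uuid")
        }
        keys = [list(r) for r in self.conn.execute(
            "SELECT key_name, key_value, uuid FROM keys "
            "ORDER BY key_name, key_value")]
        log = [
            {"tid": r[0], "updated": sorted(json.loads(r[1])),
             "renamed": sorted(json.loads(r[2]))}
            for r in self.conn.execute(
                "SELECT tid, updated, renamed FROM log ORDER BY tid")
        ]
        return {"documents": docs, "keys": keys, "log": log}

    def replay_into(self, other: "DocumentStore") -> None:
        """Re-run every logged operation against ``other`` (log completeness
        oracle)."""
        for record in self.transactions_since(0):
            for op in record.operations:
                if op["op"] == "create":
                    other.create_item(op["item_type"], op["properties"])
                elif op["op"] == "update":
                    other.update_item(op["identifier"], op["delta"],
                                      mode=op["mode"])

    # ------------------------------------------------------------------
    # internals

    def _uuid_exists(self, uid: str) -> bool:
        return self.conn.execute(
            "SELECT 1 FROM documents WHERE uuid = ?", (uid,)
        ).fetchone() is not None

    def _apply_server_defaults(self, schema, props: dict) -> dict:
        for name, spec in schema.properties_spec.items():
            if name in props or not isinstance(spec, dict):
                continue
            if spec.get("serverDefault") == "accession":
                props[name] = self._mint_accession(schema)
            elif "default" in spec:
                props[name] = spec["default"]
        return props

    def _mint_accession(self, schema) -> str:
        code = schema.accession_code or "XX"
        i = self.conn.execute(
            "SELECT COUNT(*) FROM documents WHERE item_type = ?",
            (schema.item_type,),
        ).fetchone()[0]
        while True:
            digits, letters = divmod(i, 17576)
            candidate = f"TST{code}{digits:03d}{_letters3(letters)}"
            hit = self.conn.execute(
                "SELECT 1 FROM keys WHERE key_name = 'accession' AND "
                "key_value = ?", (candidate,)
            ).fetchone()
            if hit is None:
                return candidate
            i += 1

    def _resolve_links(self, schema, props: dict) -> tuple[dict, set]:
        """Normalize link values to uuids; verify referential integrity."""
        targets: set[str] = set()
        resolved = dict(props)
        for name, target_type in schema.link_fields.items():
            if name not in props or props[name] is None:
                continue
            value = props[name]
            if schema.is_list_link(name):
                resolved[name] = [
                    self._resolve_one_link(name, v, target_type, targets)
                    for v in value
                ]
            else:
                resolved[name] = self._resolve_one_link(
                    name, value, target_type, targets
                )
        return resolved, targets

    def _resolve_one_link(self, name, token, target_type, targets) -> str:
        try:
            found_type, uid = self.resolve_identifier(str(token))
        except UnresolvableToken:
            raise DanglingLink(
                f"link property {name!r} target {token!r} does not exist"
            ) from None
        if found_type != target_type:
            raise DanglingLink(
                f"link property {name!r} target {token!r} is a {found_type}, "
                f"expected {target_type}"
            )
        targets.add(uid)
        return uid

    def _register_keys(self, keys, uid):
        for key_name, key_value in keys:
            self.conn.execute(
                "INSERT INTO keys VALUES (?, ?, ?)", (key_name, key_value, uid)
            )

    def _append_log(self, updated, renamed, operations):
        self.conn.execute(
            "INSERT INTO log (updated, renamed, timestamp, operations) "
            "VALUES (?, ?, ?, ?)",
            (
                json.dumps(sorted(updated)),
                json.dumps(sorted(renamed)),
                datetime.datetime.now(datetime.timezone.utc).isoformat(),
                json.dumps(operations, sort_keys=True),
            ),
        )
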