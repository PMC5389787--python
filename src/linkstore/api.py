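"""HTTP surface: item/collection endpoints, frame selection, write semantics
with validation status codes, and the four-tier permission model
(admin | submitter | consortium | base).

``Service.handle_request`` is a pure function from (method, path, query,
body, principal) to (status code, JSON body); ``make_wsgi_app`` adapts it to
WSGI with content negotiation (``format=json`` or a JSON Accept header
selects JSON, otherwise an HTML placeholder wraps the same JSON — the URLs
are identical either way).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from . import fixtures
from .audits import AuditEngine
from .errors import (
    DanglingLink,
    DuplicateKey,
    NotFound,
    PermissionDenied,
    UnknownType,
    ValidationFailure,
)
from .indexing import Indexer
from .rendering import FRAMES, Renderer
from .schemas import SchemaRegistry
from .storage import Document, DocumentStore

TIERS = ("admin", "submitter", "consortium", "base")


@dataclass(frozen=True)
class Principal:
    user_id: str = "anonymous"
    tier: str = "base"
    lab_groups: frozenset = field(default_factory=frozenset)
    project_scope: str | None = None

    def __post_init__(self):
        if self.tier not in TIERS:
            raise ValueError(f"unknown tier {self.tier!r}")
        if self.user_id == "anonymous" and (
                self.tier != "base" or self.lab_groups):
            raise ValueError("anonymous principals are tier base with no labs")


ANONYMOUS = Principal()


@dataclass(frozen=True)
class AccessDecision:
    action: str
    allowed: bool
    reason: str


def authorize(principal: Principal, *, action: str, status: str,
              lab: str | None, project: str | None) -> AccessDecision:
    """Pure tier/status/lab/project decision for view | edit | create."""
    if principal.tier == "admin":
        return AccessDecision(action, True, "admin")
    if action == "view":
        if status == "released":
            return AccessDecision(action, True, "released-public")
        if status == "deleted":
            return AccessDecision(action, False, "deleted")
        if principal.tier in ("submitter", "consortium"):
            if project is None or principal.project_scope == project:
                return AccessDecision(action, True, "consortium-unreleased")
            return AccessDecision(action, False, "cross-project")
        return AccessDecision(action, False, "unreleased")
    if action in ("edit", "create"):
        if principal.tier != "submitter":
            return AccessDecision(action, False, "tier")
        if lab is None or lab not in principal.lab_groups:
            return AccessDecision(action, False, "lab-membership")
        if action == "edit" and status in ("released", "deleted"):
            return AccessDecision(action, False, "released-locked")
        return AccessDecision(action, True, "submitter-lab")
    return AccessDecision(action, False, "unknown-action")


class Service:
    """Wires registry, store, renderer, indexer and audit engine together
    behind the request handler."""

    def __init__(self, registry: SchemaRegistry | None = None,
                 db_path: str = ":memory:",
                 embeds: dict | None = None,
                 read_depth_minimums: dict | None = None):
        self.registry = registry or fixtures.default_registry()
        self.store = DocumentStore(self.registry, db_path, acl=self._store_acl)
        self.renderer = Renderer(
            self.store,
            embeds=fixtures.DEFAULT_EMBEDS if embeds is None else embeds,
            calculated=fixtures.default_calculated(),
        )
        self.audit_engine = AuditEngine(self.renderer)
        for rule in fixtures.builtin_audit_rules(read_depth_minimums):
            if rule.item_type in self.registry:
                self.audit_engine.register_rule(rule)
        self.indexer = Indexer(self.store, self.renderer)

    # -- permissions ----------------------------------------------------

    def _document_scope(self, properties: dict) -> tuple[str | None, str | None]:
        """(lab uuid, project) governing the document's permissions."""
        lab = properties.get("lab")
        if isinstance(lab, dict):  # embedded rendering
            lab = lab.get("uuid") or lab.get("@id")
        if lab is not None:
            try:
                _, lab = self.store.resolve_identifier(str(lab))
            except NotFound:
                lab = None
        project = properties.get("project")
        award = properties.get("award")
        if project is None and isinstance(award, dict):
            project = award.get("project")
        elif project is None and award is not None:
            try:
                award_doc = self.store.get_item(str(award))
                project = award_doc.properties.get("project")
            except NotFound:
                project = None
        return lab, project

    def _decide(self, principal, action, properties) -> AccessDecision:
        lab, project = self._document_scope(properties)
        return authorize(principal or ANONYMOUS, action=action,
                         status=properties.get("status", "in progress"),
                         lab=lab, project=project)

    def _store_acl(self, principal, action, item_type, properties):
        if principal is None:  # direct library use bypasses the ACL
            return
        if not self._decide(principal, action, properties).allowed:
            raise PermissionDenied(f"{action} {item_type} denied")

    def can_view(self, principal, document: Document) -> bool:
        return self._decide(principal, "view", document.properties).allowed

    # -- lifecycle ------------------------------------------------------

    def load_fixture(self, config=None, **kwargs) -> dict:
        config = config or fixtures.FixtureConfig(**kwargs)
        return fixtures.load_fixture(config, self.store)

    def reindex(self) -> int:
        return self.indexer.run_index_pass()

    # -- request handling -----------------------------------------------

    def handle_request(self, method: str, url_path: str,
                       query: dict | None = None, body: dict | None = None,
                       principal: Principal | None = None):
        """Returns ``(status code, JSON-able body)``."""
        principal = principal or ANONYMOUS
        query = {k: v for k, v in (query or {}).items()}
        method = method.upper()
        segments = [s for s in url_path.split("/") if s]
        try:
            if segments[:1] == ["profiles"]:
                return self._profiles(segments)
            if segments[:1] == ["search"]:
                return self._search(query, principal)
            if len(segments) == 1:
                item_type = self.registry.type_for_collection(segments[0])
                if item_type is not None:
                    if method == "GET":
                        return self._collection(item_type, principal, query)
                    if method == "POST":
                        return self._create(item_type, body, principal)
                    return 405, {"error": f"{method} not allowed here"}
                # bare accession/uuid alias
                return self._item(segments[0], method, query, body, principal)
            if len(segments) == 2:
                item_type = self.registry.type_for_collection(segments[0])
                if item_type is None:
                    return 404, {"error": f"no collection {segments[0]!r}"}
                return self._item(segments[1], method, query, body, principal,
                                  expect_type=item_type)
            return 404, {"error": "not found"}
        except NotFound:
            return 404, {"error": "not found"}

    # -- endpoint bodies -------------------------------------------------

    def _profiles(self, segments):
        if len(segments) == 1:
            return 200, self.registry.profiles()
        name = segments[1]
        if name.endswith(".json"):
            name = name[:-5]
        try:
            return 200, self.registry.profiles(name)
        except UnknownType:
            return 404, {"error": f"unknown type {name!r}"}

    def _search(self, query, principal):
        reserved = {"type", "limit", "frame", "format", "sort"}
        filters = {k: (v[0] if isinstance(v, list) and len(v) == 1 else v)
                   for k, v in query.items() if k not in reserved}
        type_filter = _scalar(query.get("type"))
        if type_filter and type_filter not in self.registry:
            by_title = {self.registry[t].title.replace(" ", ""): t
                        for t in self.registry.types}
            type_filter = by_title.get(type_filter, type_filter)
        limit = _scalar(query.get("limit")) or "all"
        result = self.indexer.search(
            filters=filters, type_filter=type_filter,
            visible=lambda record: self._decide(
                principal, "view", record.body).allowed,
            limit=limit)
        return 200, {"@graph": result.records, "facets": result.facets,
                     "total": result.total}

    def _collection(self, item_type, principal, query):
        members = []
        for document in self.store.items_of_type(item_type):
            if document.status == "deleted":
                continue
            if not self.can_view(principal, document):
                continue
            members.append(self.renderer.render(document.uuid, "object").body)
        schema = self.registry[item_type]
        return 200, {"@id": f"/{schema.collection}/",
                     "@type": [schema.title.replace(" ", "") + "Collection",
                               "Collection"],
                     "@graph": members, "total": len(members)}

    def _item(self, token, method, query, body, principal, expect_type=None):
        document = self.store.get_item(token)  # NotFound -> 404
        if expect_type is not None and document.item_type != expect_type:
            return 404, {"error": "not found"}
        visible = self.can_view(principal, document)
        if method == "GET":
            if not visible:
                return 404, {"error": "not found"}  # do not leak existence
            frame = _scalar(query.get("frame")) or "page"
            if frame not in FRAMES:
                return 400, {"error": f"unknown frame {frame!r}"}
            return 200, self.renderer.render(document.uuid, frame).body
        if method in ("PATCH", "PUT"):
            if not visible:
                return 404, {"error": "not found"}
            if not self._decide(principal, "edit", document.properties).allowed:
                return 403, {"error": "forbidden"}
            mode = "patch" if method == "PATCH" else "replace"
            return self._write(lambda: self.store.update_item(
                document.uuid, body or {}, mode=mode, principal=None))
        return 405, {"error": f"{method} not allowed here"}

    def _create(self, item_type, body, principal):
        if body is None:
            return 400, {"error": "request body required"}
        decision = self._decide(principal, "create", body)
        if not decision.allowed:
            return 403, {"error": "forbidden", "reason": decision.reason}
        return self._write(lambda: self.store.create_item(
            item_type, body, principal=None))

    def _write(self, op):
        try:
            document = op()
        except ValidationFailure as exc:
            return 422, {"status": "error", "code": 422,
                         "errors": exc.violations}
        except (DanglingLink, UnknownType) as exc:
            return 422, {"status": "error", "code": 422,
                         "errors": [{"name": "", "description": str(exc)}]}
        except DuplicateKey as exc:
            return 409, {"status": "error", "code": 409,
                         "errors": [{"name": "", "description": str(exc)}]}
        rendered = self.renderer.render(document.uuid, "object").body
        return 200, {"status": "success", "@graph": [rendered]}


def _scalar(value):
    if isinstance(value, list):
        return value[0] if value else None
    return value


# ---------------------------------------------------------------------------
# WSGI adapter


_HTML_ENVELOPE = """<!DOCTYPE html>
<html><head><title>linkstore</title></head>
<body><pre>{payload}</pre></body></html>
"""


def make_wsgi_app(service: Service, principal_resolver=None):
    """WSGI wrapper; principals arrive via the ``X-Test-Principal`` header
    (a JSON Principal) unless a resolver callable is supplied."""
    import html as html_mod
    from urllib.parse import parse_qs

    def resolve_principal(environ) -> Principal:
        if principal_resolver is not None:
            return principal_resolver(environ)
        raw = environ.get("HTTP_X_TEST_PRINCIPAL")
        if not raw:
            return ANONYMOUS
        data = json.loads(raw)
        return Principal(
            user_id=data.get("user_id", "anonymous"),
            tier=data.get("tier", "base"),
            lab_groups=frozenset(data.get("lab_groups", [])),
            project_scope=data.get("project_scope"),
        )

    def app(environ, start_response):
        method = environ["REQUEST_METHOD"]
        path = environ.get("PATH_INFO", "/")
        query = parse_qs(environ.get("QUERY_STRING", ""))
        body = None
        length = int(environ.get("CONTENT_LENGTH") or 0)
        if length:
            raw = environ["wsgi.input"].read(length)
            try:
                body = json.loads(raw)
            except ValueError:
                return _respond(start_response, 400,
                                {"error": "malformed JSON body"}, True)
        try:
            principal = resolve_principal(environ)
        except (ValueError, KeyError):
            return _respond(start_response, 400,
                            {"error": "bad principal header"}, True)
        status, payload = service.handle_request(
            method, path, query, body, principal)
        wants_json = ("json" in [_scalar(query.get("format"))]
                      or "application/json" in environ.get("HTTP_ACCEPT", ""))
        return _respond(start_response, status, payload, wants_json)

    def _respond(start_response, status, payload, wants_json):
        text = json.dumps(payload, sort_keys=True, indent=1)
        if wants_json:
            content_type = "application/json"
            out = text
        else:
            content_type = "text/html; charset=utf-8"
            out = _HTML_ENVELOPE.format(payload=html_mod.escape(text))
        data = out.encode("utf-8")
        start_response(
            f"{status} {_REASONS.get(status, 'OK')}",
            [("Content-Type", content_type),
             ("Content-Length", str(len(data)))],
        )
        return [data]

    return app


_REASONS = {200: "OK", 400: "Bad Request", 403: "Forbidden",
            404: "Not Found", 405: "Method Not Allowed", 409: "Conflict",
            422: "Unprocessable Entity"}
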