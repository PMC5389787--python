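"""Frame-based rendering of stored documents.

Four frames of increasing depth:

raw
    The stored (upgraded) properties verbatim, links as uuids.
object
    raw plus ``@id``/``@type``/``uuid`` metadata, canonical-path link values,
    and calculated properties (including reverse links).
embedded
    object with each configured embed path's link replaced by a copy of the
    target's object-frame rendering.
page
    embedded plus audit results grouped by severity.

Every rendering records two identifier sets: ``embedded_uuids`` — objects
whose properties were copied or consulted (any change to one of these must
invalidate the rendering) — and ``linked_uuids`` — objects referenced only by
canonical path (only a rename need invalidate).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import HookFailure, UnknownFrame, UnknownRevDeclaration
from .storage import Document, DocumentStore

FRAMES = ("raw", "object", "embedded", "page")


@dataclass
class RenderedView:
    uuid: str
    frame: str
    body: dict
    embedded_uuids: set = field(default_factory=set)
    linked_uuids: set = field(default_factory=set)


@dataclass
class EmbedSpec:
    """Dot-separated link/rev paths to expand for one item type."""

    item_type: str
    paths: list


class _RenderContext:
    """Accumulates the consulted/linked identifier sets for one rendering."""

    def __init__(self):
        self.embedded: set[str] = set()
        self.linked: set[str] = set()
        self.stack: list[str] = []  # cycle guard for embed recursion

    def finish(self):
        self.linked -= self.embedded


class CalculatedProperties:
    """Registry of per-type calculated-property hooks.

    A hook is ``fn(renderer, document, body, ctx) -> value``; reverse links
    declared in schemas are registered automatically by the renderer.
    """

    def __init__(self):
        self._hooks: dict[str, dict] = {}

    def register(self, item_type: str, name: str, fn) -> None:
        self._hooks.setdefault(item_type, {})[name] = fn

    def hooks_for(self, item_type: str) -> dict:
        return dict(sorted(self._hooks.get(item_type, {}).items()))


class Renderer:
    def __init__(self, store: DocumentStore,
                 embeds: dict[str, list] | None = None,
                 calculated: CalculatedProperties | None = None):
        self.store = store
        self.registry = store.registry
        self.embeds = {t: EmbedSpec(t, list(p))
                       for t, p in (embeds or {}).items()}
        self.calculated = calculated or CalculatedProperties()
        self.audit_engine = None  # set by the audit engine when attached

    # ------------------------------------------------------------------

    def render(self, identifier: str, frame: str = "page") -> RenderedView:
        if frame not in FRAMES:
            raise UnknownFrame(frame)
        document = self.store.get_item(identifier)
        ctx = _RenderContext()
        ctx.embedded.add(document.uuid)
        if frame == "raw":
            body = dict(document.properties)
            body["uuid"] = document.uuid
        else:
            ctx.stack.append(document.uuid)
            body = self._object_body(document, ctx)
            if frame in ("embedded", "page"):
                spec = self.embeds.get(document.item_type)
                if spec is not None:
                    self._expand(body, document.item_type, spec.paths, ctx)
            ctx.stack.pop()
            if frame == "page" and self.audit_engine is not None:
                body["audit"] = self.audit_engine.grouped_audits(
                    document.uuid, ctx
                )
        ctx.finish()
        return RenderedView(document.uuid, frame, body,
                            ctx.embedded, ctx.linked)

    # ------------------------------------------------------------------

    def _object_body(self, document: Document, ctx: _RenderContext) -> dict:
        schema = self.registry[document.item_type]
        body = dict(document.properties)
        for name in schema.link_fields:
            if name not in body or body[name] is None:
                continue
            if schema.is_list_link(name):
                body[name] = [self._link_path(v, ctx) for v in body[name]]
            else:
                body[name] = self._link_path(body[name], ctx)
        body["@id"] = self.store.canonical_path(document)
        body["@type"] = [schema.title.replace(" ", ""), "Item"]
        body["uuid"] = document.uuid
        self._add_calculated(document, body, ctx)
        return body

    def _link_path(self, uid: str, ctx: _RenderContext) -> str:
        # reading only the target's path-determining key: linked, not embedded
        target = self.store.get_item(uid)
        if uid not in ctx.embedded:
            ctx.linked.add(uid)
        return self.store.canonical_path(target)

    def _add_calculated(self, document, body, ctx) -> None:
        schema = self.registry[document.item_type]
        for name, (child_type, child_field) in sorted(
                schema.rev_fields.items()):
            children = self.rev_links(document.uuid, child_type, child_field,
                                      ctx=ctx)
            body[name] = [
                self.store.canonical_path(self.store.get_item(c))
                for c in children
            ]
        for name, fn in self.calculated.hooks_for(document.item_type).items():
            try:
                value = fn(self, document, body, ctx)
            except Exception as exc:
                raise HookFailure(name, exc) from exc
            if value is not None:
                body[name] = value

    def compute_calculated(self, item_type: str, object_body: dict) -> dict:
        """Apply calculated-property hooks to an object-frame body."""
        document = self.store.get_item(object_body["uuid"])
        ctx = _RenderContext()
        ctx.embedded.add(document.uuid)
        body = dict(object_body)
        self._add_calculated(document, body, ctx)
        return body

    # ------------------------------------------------------------------

    def rev_links(self, parent_uuid: str, child_type: str,
                  child_link_field: str, ctx=None) -> list[str]:
        """uuids of all non-deleted children whose link field targets the
        parent; ordered by accession/name key then uuid.

        Membership consults each candidate child's properties, so children
        are recorded as embedded (their updates invalidate the parent).
        """
        declared = any(
            (child_type, child_link_field) == decl
            for schema in (self.registry[t] for t in self.registry.types)
            for decl in schema.rev_fields.values()
        )
        if not declared:
            raise UnknownRevDeclaration(
                f"({child_type}, {child_link_field}) is not declared by any "
                f"rev field"
            )
        child_schema = self.registry[child_type]
        hits = []
        for child in self.store.items_of_type(child_type):
            if child.status == "deleted":
                continue
            value = child.properties.get(child_link_field)
            values = value if isinstance(value, list) else [value]
            if parent_uuid in values:
                name = ""
                if child_schema.name_key:
                    name = str(child.properties.get(child_schema.name_key, ""))
                hits.append((name, child.uuid))
                if ctx is not None:
                    ctx.embedded.add(child.uuid)
                    ctx.linked.discard(child.uuid)
        return [uid for _, uid in sorted(hits)]

    # ------------------------------------------------------------------

    def _expand(self, body: dict, item_type: str, paths: list,
                ctx: _RenderContext) -> None:
        """Replace link values along embed paths with object-frame copies."""
        schema = self.registry[item_type]
        heads: dict[str, list] = {}
        for path in paths:
            head, _, tail = path.partition(".")
            heads.setdefault(head, [])
            if tail:
                heads[head].append(tail)
        for head, tails in heads.items():
            if head in schema.rev_fields:
                child_type = schema.rev_fields[head][0]
            elif head in schema.link_fields:
                child_type = schema.link_fields[head]
            else:
                raise UnknownRevDeclaration(
                    f"embed path segment {head!r} is not a link or rev field "
                    f"of {item_type}"
                )
            if head not in body or body[head] is None:
                continue
            value = body[head]
            if isinstance(value, list):
                body[head] = [self._embed_target(v, child_type, tails, ctx)
                              for v in value]
            else:
                body[head] = self._embed_target(value, child_type, tails, ctx)

    def _embed_target(self, path_value: str, child_type: str, tails: list,
                      ctx: _RenderContext):
        _, uid = self.store.resolve_identifier(path_value)
        if uid in ctx.stack:
            # cycle: fall back to a canonical-path reference
            if uid not in ctx.embedded:
                ctx.linked.add(uid)
            return path_value
        document = self.store.get_item(uid)
        ctx.embedded.add(uid)
        ctx.linked.discard(uid)
        ctx.stack.append(uid)
        sub = self._object_body(document, ctx)
        if tails:
            self._expand(sub, child_type, tails, ctx)
        ctx.stack.pop()
        return sub
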