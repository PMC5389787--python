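"""Incremental index of page-frame documents, kept consistent with the store
by the invalidation rubric:

With U = union of updated_uuids and R = union of renamed_uuids over every
transaction since the last pass, the records to reindex are::

    invalidated = U  ∪  { r : r.embedded_uuids ∩ U  or  r.linked_uuids ∩ R }

The backend is an in-process mapping with the same contract a server-grade
search engine would satisfy; batch (pull) passes driven by the transaction
log make the process deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .errors import NotFound
from .rendering import Renderer
from .storage import DocumentStore


@dataclass
class IndexRecord:
    uuid: str
    item_type: str
    body: dict
    embedded_uuids: set
    linked_uuids: set
    audit: list
    indexed_tid: int


@dataclass
class InvalidationReport:
    updated: set
    renamed: set
    invalidated: set


@dataclass
class SearchResult:
    records: list
    facets: dict
    total: int


class Indexer:
    def __init__(self, store: DocumentStore, renderer: Renderer):
        self.store = store
        self.renderer = renderer
        self.records: dict[str, IndexRecord] = {}
        self.last_tid = 0
        self.failures: list = []

    # ------------------------------------------------------------------

    def invalidated_since(self, last_tid: int) -> InvalidationReport:
        updated: set[str] = set()
        renamed: set[str] = set()
        for txn in self.store.transactions_since(last_tid):
            updated |= txn.updated_uuids
            renamed |= txn.renamed_uuids
        invalidated = set(updated)
        if updated or renamed:
            for record in self.records.values():
                if record.embedded_uuids & updated:
                    invalidated.add(record.uuid)
                elif record.linked_uuids & renamed:
                    invalidated.add(record.uuid)
        return InvalidationReport(updated, renamed, invalidated)

    def run_index_pass(self) -> int:
        """Render the page frame for every invalidated identifier and swap
        the records in; deleted documents leave the index. Returns the number
        of records refreshed or removed; 0 when caught up."""
        head = self.store.head_tid()
        report = self.invalidated_since(self.last_tid)
        count = 0
        self.failures = []
        for uid in sorted(report.invalidated):
            try:
                document = self.store.get_item(uid)
            except NotFound:
                document = None
            if document is None or document.status == "deleted":
                if self.records.pop(uid, None) is not None:
                    count += 1
                continue
            try:
                view = self.renderer.render(uid, "page")
            except Exception as exc:  # render-failure: report, continue
                self.failures.append((uid, exc))
                continue
            audit = [f for group in view.body.get("audit", {}).values()
                     for f in group]
            self.records[uid] = IndexRecord(
                uuid=uid,
                item_type=document.item_type,
                body=view.body,
                embedded_uuids=set(view.embedded_uuids),
                linked_uuids=set(view.linked_uuids),
                audit=audit,
                indexed_tid=head,
            )
            count += 1
        self.last_tid = head
        return count

    # ------------------------------------------------------------------

    def search(self, filters: dict | None = None,
               type_filter: str | None = None,
               visible=None,
               limit: int | str = "all") -> SearchResult:
        """Exact-match filtered search with per-type facet aggregations.

        ``visible`` is an optional predicate over IndexRecord applied before
        anything else (the REST layer passes its ACL closure).
        """
        filters = dict(filters or {})
        matching = []
        for uid in sorted(self.records):
            record = self.records[uid]
            if type_filter and record.item_type != type_filter:
                continue
            if visible is not None and not visible(record):
                continue
            if all(self._matches(record.body, path, wanted)
                   for path, wanted in filters.items()):
                matching.append(record)
        facets = {}
        if type_filter and type_filter in self.store.registry:
            schema = self.store.registry[type_filter]
            for path, config in schema.facet_config.items():
                if not self._facet_known(schema, path):
                    warnings.warn(
                        f"facet field {path!r} is not part of the "
                        f"{type_filter} schema; ignored", stacklevel=2)
                    continue
                counts: dict[str, int] = {}
                for record in matching:
                    for value in self._values_at(record.body, path):
                        counts[str(value)] = counts.get(str(value), 0) + 1
                title = config.get("title", path) if isinstance(config, dict) \
                    else str(config)
                facets[path] = {"title": title, "terms": dict(sorted(
                    counts.items()))}
        records = matching if limit in ("all", None) else matching[:int(limit)]
        return SearchResult([r.body for r in records], facets, len(matching))

    # ------------------------------------------------------------------

    @staticmethod
    def _values_at(body, path):
        parts = path.split(".")
        nodes = [body]
        for part in parts:
            next_nodes = []
            for node in nodes:
                if isinstance(node, list):
                    node_items = node
                else:
                    node_items = [node]
                for item in node_items:
                    if isinstance(item, dict) and part in item:
                        next_nodes.append(item[part])
            nodes = next_nodes
        out = []
        for node in nodes:
            if isinstance(node, list):
                out.extend(node)
            else:
                out.append(node)
        return [v for v in out if not isinstance(v, (dict, list))]

    @classmethod
    def _matches(cls, body, path, wanted) -> bool:
        values = cls._values_at(body, path)
        wanted_list = wanted if isinstance(wanted, list) else [wanted]
        return any(str(v) == str(w) for v in values for w in wanted_list)

    @staticmethod
    def _facet_known(schema, path) -> bool:
        head = path.split(".", 1)[0]
        return (head in schema.properties_spec or head in schema.rev_fields
                or head in ("@id", "@type", "uuid"))
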