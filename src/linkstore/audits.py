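"""Cross-object integrity audits.

Rules are small predicates evaluated against an object's embedded rendering
whenever it is (re)indexed; because a predicate may read only that rendering,
every document it consults is already in the rendering's embedded_uuids and
stored audit results can never go stale under the invalidation rubric.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

SEVERITIES = ("ERROR", "WARNING", "NOT_COMPLIANT", "INTERNAL_ACTION")


@dataclass(frozen=True)
class AuditResult:
    severity: str
    category: str
    detail: str
    path: str

    def __post_init__(self):
        if self.severity not in SEVERITIES:
            raise ValueError(f"unknown severity {self.severity!r}")

    def to_json(self) -> dict:
        return {"severity": self.severity, "category": self.category,
                "detail": self.detail, "path": self.path}

    @classmethod
    def from_json(cls, data: dict) -> "AuditResult":
        return cls(data["severity"], data["category"], data["detail"],
                   data["path"])


@dataclass
class AuditRule:
    """``predicate(embedded_body)`` returns zero or more detail strings (or
    AuditResults) describing findings on the rendered object."""

    item_type: str
    category: str
    severity: str
    predicate: Callable


class AuditEngine:
    def __init__(self, renderer):
        self.renderer = renderer
        self.registry = renderer.registry
        self._rules: dict[tuple[str, str], AuditRule] = {}
        renderer.audit_engine = self

    def register_rule(self, rule: AuditRule) -> tuple[str, str]:
        """Duplicate (type, category) registration replaces the old rule."""
        self.registry[rule.item_type]  # raises UnknownType
        handle = (rule.item_type, rule.category)
        self._rules[handle] = rule
        return handle

    def rules_for(self, item_type: str):
        return sorted(
            (rule for (t, _), rule in self._rules.items() if t == item_type),
            key=lambda r: r.category,
        )

    # ------------------------------------------------------------------

    def run_audits(self, identifier: str) -> list[AuditResult]:
        """Evaluate every rule for the document's type against its embedded
        rendering; rule crashes become INTERNAL_ACTION findings, never fatal.
        """
        document = self.renderer.store.get_item(identifier)
        view = self.renderer.render(document.uuid, "embedded")
        return self._evaluate(document.item_type, view.body)

    def grouped_audits(self, identifier: str, ctx=None) -> dict:
        """Findings grouped by severity, as attached to the page frame.

        When called from inside a page render, ``ctx`` receives the uuids the
        audit rendering consulted, keeping the page record's dependency sets
        complete.
        """
        document = self.renderer.store.get_item(identifier)
        view = self.renderer.render(document.uuid, "embedded")
        if ctx is not None:
            ctx.embedded |= view.embedded_uuids
            ctx.linked |= view.linked_uuids
        grouped: dict[str, list] = {}
        for finding in self._evaluate(document.item_type, view.body):
            grouped.setdefault(finding.severity, []).append(finding.to_json())
        return grouped

    def _evaluate(self, item_type: str, embedded_body: dict):
        path = embedded_body.get("@id", "")
        findings: list[AuditResult] = []
        for rule in self.rules_for(item_type):
            try:
                raised = rule.predicate(embedded_body) or []
            except Exception as exc:
                findings.append(AuditResult(
                    "INTERNAL_ACTION", rule.category,
                    f"audit rule {rule.category!r} failed: {exc}", path))
                continue
            for item in raised:
                if isinstance(item, AuditResult):
                    findings.append(item)
                else:
                    findings.append(AuditResult(
                        rule.severity, rule.category, str(item), path))
        findings.sort(key=lambda f: (f.category, f.path, f.detail))
        return findings
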