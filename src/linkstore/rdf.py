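"""Convert the object-frame document graph to RDF triples.

Export operates on the object frame only: link values become resource URIs
referencing — never duplicating — the linked documents. Sub-objects without
identity are flattened with dotted predicate names; no blank nodes are
emitted, so serializations are deterministic and diffable.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import UnknownSyntax

RDF_TYPE = "http://www.w3.org/1999/02/22-rdf-syntax-ns#type"
XSD = "http://www.w3.org/2001/XMLSchema#"


@dataclass(frozen=True)
class URIRef:
    value: str


@dataclass(frozen=True)
class Literal:
    value: str
    datatype: str | None = None


@dataclass(frozen=True)
class Triple:
    subject: URIRef
    predicate: URIRef
    object: object  # URIRef | Literal


def _literal(value) -> Literal:
    if isinstance(value, bool):
        return Literal("true" if value else "false", XSD + "boolean")
    if isinstance(value, int):
        return Literal(str(value), XSD + "integer")
    if isinstance(value, float):
        return Literal(repr(value), XSD + "double")
    return Literal(str(value))


def graph_to_triples(object_bodies, base_uri: str,
                     vocab_uri: str | None = None) -> set[Triple]:
    """One triple per scalar leaf (literal), per link value (resource URI)
    and one rdf:type triple per document.

    A string value is a link iff it is the canonical path (``@id``) of a
    document in the exported set.
    """
    base_uri = base_uri.rstrip("/")
    vocab = (vocab_uri or base_uri + "/terms#").rstrip("#") + "#"
    bodies = list(object_bodies)
    known_paths = {body["@id"] for body in bodies}
    triples: set[Triple] = set()

    def to_object(value):
        if isinstance(value, str) and value in known_paths:
            return URIRef(base_uri + value)
        return _literal(value)

    def walk(subject, predicate_name, value):
        if isinstance(value, dict):
            for key, sub in value.items():
                walk(subject, f"{predicate_name}.{key}", sub)
        elif isinstance(value, list):
            for element in value:
                walk(subject, predicate_name, element)
        elif value is not None:
            triples.add(Triple(subject, URIRef(vocab + predicate_name),
                               to_object(value)))

    for body in bodies:
        subject = URIRef(base_uri + body["@id"])
        type_name = body.get("@type", ["Item"])[0]
        triples.add(Triple(subject, URIRef(RDF_TYPE), URIRef(vocab + type_name)))
        for key, value in body.items():
            if key in ("@id", "@type", "audit"):
                continue
            walk(subject, key, value)
    return triples


# ---------------------------------------------------------------------------
# serialization


def _escape(text: str) -> str:
    return (text.replace("\\", "\\\\").replace('"', '\\"')
            .replace("\n", "\\n").replace("\r", "\\r").replace("\t", "\\t"))


def _term_nt(term) -> str:
    if isinstance(term, URIRef):
        return f"<{term.value}>"
    if term.datatype:
        return f'"{_escape(term.value)}"^^<{term.datatype}>'
    return f'"{_escape(term.value)}"'


def serialize(triples, syntax: str = "ntriples") -> str:
    if syntax == "ntriples":
        return _serialize_ntriples(triples)
    if syntax == "turtle":
        return _serialize_turtle(triples)
    raise UnknownSyntax(syntax)


def _sorted(triples):
    return sorted(triples, key=lambda t: (
        t.subject.value, t.predicate.value, _term_nt(t.object)))


def _serialize_ntriples(triples) -> str:
    return "".join(
        f"{_term_nt(t.subject)} {_term_nt(t.predicate)} "
        f"{_term_nt(t.object)} .\n"
        for t in _sorted(triples)
    )


def _serialize_turtle(triples) -> str:
    lines = []
    by_subject: dict[str, list] = {}
    for t in _sorted(triples):
        by_subject.setdefault(t.subject.value, []).append(t)
    for subject in sorted(by_subject):
        group = by_subject[subject]
        lines.append(f"<{subject}>")
        for i, t in enumerate(group):
            terminator = " ;" if i < len(group) - 1 else " ."
            lines.append(
                f"    {_term_nt(t.predicate)} {_term_nt(t.object)}{terminator}")
        lines.append("")
    return "\n".join(lines)
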