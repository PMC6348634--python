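"""Readers, writers, RDF export, and perspective-based graph filtering.

Assertion files come in two dialects:

* TSV — four columns ``subject  predicate  object  object_kind`` with a
  version header; entity declarations use the pseudo-predicate ``declare``
  (object = display label) and asserted types the pseudo-predicate ``type``.
* JSON — a mirror of the same content under ``entities`` / ``assertions``.

RDF export emits Turtle through a canonical serializer (stable prefixes,
sorted triples, one triple per line) so that identical inputs always
produce byte-identical documents; re-import goes through rdflib.
"""

from __future__ import annotations

import csv
import io as _io
import json
import re
from typing import Iterable, Optional

import rdflib

from .classification import ClassificationResult, RepresentationChain
from .core import (
    Assertion,
    AssertionSet,
    CategoryTaxonomy,
    EntityInstance,
    PREDICATES,
)
from .partition import GranularityTree
from .perspectives import LevelAssignment, PerspectiveRegistry

TSV_VERSION = "domgran-assertions v1"
_PSEUDO = ("declare", "type")

NS = "https://w3id.org/domgran#"

#: Relation resources whose canonical local names differ from the conventional
#: spelling (kept as rdfs:label).
RELATION_LOCAL_NAMES = {
    "Hist/EvGranRep": "hist_ev_gran_rep",
    "Hist/EvSp-StrGranRep": "hist_ev_sp_str_gran_rep",
}


class DialectError(ValueError):
    pass


# --------------------------------------------------------------------------
# Assertion TSV / JSON
# --------------------------------------------------------------------------

def write_assertions_tsv(aset: AssertionSet) -> str:
    buf = _io.StringIO()
    buf.write(f"# {TSV_VERSION}\n")
    buf.write("subject\tpredicate\tobject\tobject_kind\n")
    rows: list[tuple[str, str, str, str]] = []
    for e in aset.sorted_entities():
        rows.append((e.id, "declare", e.label, "label"))
        for t in sorted(e.asserted_types):
            rows.append((e.id, "type", t, "category"))
    kind = {"directProperPartOf": "entity", "properPartOf": "entity",
            "connectedTo": "entity", "hasPhysicalCovering": "covering",
            "bearsFunction": "function", "sharesOrigin": "origin"}
    for a in sorted(aset.assertions,
                    key=lambda a: (a.subject, a.predicate, a.object)):
        rows.append((a.subject, a.predicate, a.object, kind[a.predicate]))
    for row in rows:
        buf.write("\t".join(row) + "\n")
    return buf.getvalue()


def read_assertions_tsv(text: str) -> AssertionSet:
    lines = text.splitlines()
    if not lines or TSV_VERSION not in lines[0]:
        raise DialectError(f"missing version header {TSV_VERSION!r}")
    reader = csv.reader(lines[1:], delimiter="\t")
    header = next(reader, None)
    if header != ["subject", "predicate", "object", "object_kind"]:
        raise DialectError(f"unexpected column header: {header}")

    entities: dict[str, dict] = {}
    facts: list[tuple[int, str, str, str]] = []
    for lineno, row in enumerate(reader, start=3):
        if not row or (len(row) == 1 and not row[0].strip()):
            continue
        if len(row) != 4:
            raise DialectError(f"line {lineno}: expected 4 columns, "
                               f"got {len(row)}")
        subject, predicate, obj, _kind = row
        if predicate == "declare":
            entities.setdefault(subject, {"label": obj, "types": set()})
            entities[subject]["label"] = obj
        elif predicate == "type":
            entities.setdefault(subject, {"label": "", "types": set()})
            entities[subject]["types"].add(obj)
        elif predicate in PREDICATES:
            facts.append((lineno, subject, predicate, obj))
        else:
            raise DialectError(
                f"line {lineno}: unregistered predicate {predicate!r}")

    aset = AssertionSet(
        EntityInstance(eid, d["label"], frozenset(d["types"]))
        for eid, d in sorted(entities.items()))
    for lineno, subject, predicate, obj in facts:
        try:
            aset.add_assertion(Assertion(subject, predicate, obj))
        except ValueError as exc:
            raise DialectError(f"line {lineno}: {exc}") from exc
    return aset


def write_assertions_json(aset: AssertionSet) -> str:
    doc = {
        "version": 1,
        "entities": [
            {"id": e.id, "label": e.label,
             "types": sorted(e.asserted_types)}
            for e in aset.sorted_entities()],
        "assertions": [
            {"subject": a.subject, "predicate": a.predicate,
             "object": a.object}
            for a in sorted(aset.assertions,
                            key=lambda a: (a.subject, a.predicate,
                                           a.object))],
    }
    return json.dumps(doc, indent=1, sort_keys=True) + "\n"


def read_assertions_json(text: str) -> AssertionSet:
    doc = json.loads(text)
    if doc.get("version") != 1:
        raise DialectError(f"unsupported version: {doc.get('version')!r}")
    aset = AssertionSet(
        EntityInstance(e["id"], e.get("label", ""),
                       frozenset(e.get("types", ())))
        for e in doc["entities"])
    for i, a in enumerate(doc["assertions"]):
        try:
            aset.add_assertion(
                Assertion(a["subject"], a["predicate"], a["object"]))
        except ValueError as exc:
            raise DialectError(f"assertion #{i}: {exc}") from exc
    return aset


def read_assertions(path: str, dialect: Optional[str] = None) -> AssertionSet:
    """Load an assertion file; the dialect defaults to the file suffix."""
    with open(path, encoding="utf-8") as fh:
        text = fh.read()
    dialect = dialect or ("json" if path.endswith(".json") else "tsv")
    if dialect == "tsv":
        return read_assertions_tsv(text)
    if dialect == "json":
        return read_assertions_json(text)
    raise DialectError(f"unknown dialect: {dialect!r}")


def write_assertions(aset: AssertionSet, path: str,
                     dialect: Optional[str] = None) -> None:
    dialect = dialect or ("json" if path.endswith(".json") else "tsv")
    text = (write_assertions_json(aset) if dialect == "json"
            else write_assertions_tsv(aset))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(text)


# --------------------------------------------------------------------------
# Tree JSON / TSV
# --------------------------------------------------------------------------

def tree_to_json(tree: GranularityTree) -> str:
    doc = {
        "root": tree.root,
        "parent": {k: tree.parent[k] for k in sorted(tree.parent)},
        "extent": {k: sorted(tree.extent[k]) for k in sorted(tree.extent)},
    }
    return json.dumps(doc, indent=1, sort_keys=True) + "\n"


def tree_from_json(text: str) -> GranularityTree:
    doc = json.loads(text)
    parent = dict(doc["parent"])
    depth = {doc["root"]: 0}
    pending = dict(parent)
    while pending:
        progressed = False
        for child, par in list(pending.items()):
            if par in depth:
                depth[child] = depth[par] + 1
                del pending[child]
                progressed = True
        if not progressed:
            raise DialectError(f"disconnected nodes: {sorted(pending)}")
    extent = {k: frozenset(v) for k, v in doc["extent"].items()}
    return GranularityTree(doc["root"], parent, depth, extent)


def tree_to_edge_tsv(tree: GranularityTree) -> str:
    lines = ["child\tparent"]
    for child in sorted(tree.parent):
        lines.append(f"{child}\t{tree.parent[child]}")
    return "\n".join(lines) + "\n"


# --------------------------------------------------------------------------
# Canonical Turtle
# --------------------------------------------------------------------------

_PREFIXES = {
    "dg": NS,
    "rdf": "http://www.w3.org/1999/02/22-rdf-syntax-ns#",
    "rdfs": "http://www.w3.org/2000/01/rdf-schema#",
    "owl": "http://www.w3.org/2002/07/owl#",
}
_LOCAL_RE = re.compile(r"^[A-Za-z_][A-Za-z0-9_-]*$")


def _iri_local(name: str) -> str:
    name = RELATION_LOCAL_NAMES.get(name, name)
    return (name.replace("/", "_").replace("@", "__").replace(" ", "_")
            .replace("(", "").replace(")", "").replace("|", "_or_")
            .replace("[", "_").replace("]", ""))


def _term(value) -> str:
    if isinstance(value, rdflib.Literal) or (
            not isinstance(value, rdflib.URIRef)
            and not str(value).startswith("http")):
        escaped = str(value).replace("\\", "\\\\").replace('"', '\\"')
        return f'"{escaped}"'
    iri = str(value)
    for prefix, base in _PREFIXES.items():
        if iri.startswith(base):
            local = iri[len(base):]
            if _LOCAL_RE.match(local):
                return f"{prefix}:{local}"
    return f"<{iri}>"


def serialize_canonical(triples: Iterable[tuple]) -> str:
    """Byte-stable Turtle: sorted prefixes, sorted triples, one per line."""
    lines = [f"@prefix {p}: <{ns}> ." for p, ns in sorted(_PREFIXES.items())]
    lines.append("")
    body = sorted({f"{_term(s)} {_term(p)} {_term(o)} ."
                   for s, p, o in triples})
    return "\n".join(lines + body) + "\n"


def _dg(name: str) -> rdflib.URIRef:
    return rdflib.URIRef(NS + _iri_local(name))


RDF = rdflib.RDF
RDFS = rdflib.RDFS
OWL = rdflib.OWL


def taxonomy_triples(tax: CategoryTaxonomy) -> list[tuple]:
    triples: list[tuple] = []
    for name, node in tax.nodes.items():
        subject = _dg(name)
        triples.append((subject, RDF.type, OWL.Class))
        triples.append((subject, RDFS.label, rdflib.Literal(node.label)))
        if node.parent is not None:
            triples.append((subject, RDFS.subClassOf, _dg(node.parent)))
        for sib in tax.disjoint_siblings(name):
            if name < sib:  # one symmetric pair per edge
                triples.append((subject, OWL.disjointWith, _dg(sib)))
    return triples


def registry_triples(registry: PerspectiveRegistry) -> list[tuple]:
    triples: list[tuple] = []
    for p in registry:
        subject = _dg(f"perspective_{p.id}")
        triples.append((subject, RDF.type, _dg("GranularPerspective")))
        triples.append((subject, RDFS.label, rdflib.Literal(p.id)))
        triples.append((subject, _dg("family"), rdflib.Literal(p.family)))
        triples.append((subject, _dg("granularityType"),
                        rdflib.Literal(p.granularity_type)))
        triples.append((subject, _dg("granulationRelation"),
                        _dg(p.criterion.relation)))
        triples.append((subject, _dg("levelCountPolicy"),
                        rdflib.Literal(p.level_count_policy)))
        for i, level in enumerate(p.levels, start=1):
            lres = _dg(f"level_{p.id}_{i}")
            triples.append((lres, RDF.type, _dg("GranularityLevel")))
            triples.append((lres, _dg("inPerspective"), subject))
            triples.append((lres, _dg("levelOrdinal"),
                            rdflib.Literal(str(i))))
            triples.append((lres, RDFS.label, rdflib.Literal(level)))
    return triples


def classification_triples(
        classifications: dict[str, ClassificationResult],
        chains: dict[str, RepresentationChain] | None = None) -> list[tuple]:
    triples: list[tuple] = []
    for eid, cls in classifications.items():
        subject = _dg(f"entity_{eid}")
        for frame, cat in cls.per_frame.items():
            triples.append((subject, _dg(f"categoryAt_{frame.name}"),
                            _dg(cat)))
    for chain in (chains or {}).values():
        subject = _dg(f"entity_{chain.entity_id}")
        for fine, coarse, rel, _, _ in chain.links:
            triples.append((subject, _dg(rel),
                            _dg(f"entity_{chain.entity_id}"
                                f"__at_{coarse.name}")))
        for rel, cat in chain.side_links:
            triples.append((subject, _dg(rel), _dg(cat)))
    return triples


def export_turtle(taxonomy: CategoryTaxonomy | None = None,
                  registry: PerspectiveRegistry | None = None,
                  classifications: dict[str, ClassificationResult]
                  | None = None,
                  chains: dict[str, RepresentationChain] | None = None
                  ) -> str:
    """Canonical Turtle for any combination of framework components."""
    triples: list[tuple] = []
    if taxonomy is not None:
        triples += taxonomy_triples(taxonomy)
    if registry is not None:
        triples += registry_triples(registry)
    if classifications is not None:
        triples += classification_triples(classifications, chains)
    return serialize_canonical(triples)


def reserialize_turtle(text: str) -> str:
    """Parse Turtle with rdflib and re-emit canonically (round-trip check)."""
    g = rdflib.Graph()
    g.parse(data=text, format="turtle")
    return serialize_canonical(g)


def registry_to_json(registry: PerspectiveRegistry) -> str:
    doc = [
        {"id": p.id, "family": p.family,
         "criterion": {"relation": p.criterion.relation,
                       "domain": p.criterion.domain_category,
                       "range": p.criterion.range_category},
         "granularity_type": p.granularity_type,
         "level_count_policy": p.level_count_policy,
         "levels": list(p.levels)}
        for p in sorted(registry, key=lambda p: p.id)]
    return json.dumps(doc, indent=1, sort_keys=True) + "\n"


# --------------------------------------------------------------------------
# Perspective filter
# --------------------------------------------------------------------------

def filter_by_perspective(aset: AssertionSet,
                          assignments: LevelAssignment,
                          perspective_id: str,
                          registry: PerspectiveRegistry) -> AssertionSet:
    """Reduce a graph to one perspective's entities and granulation links.

    Keeps exactly the entities assigned to some level of the perspective
    plus the granulation-relation assertions connecting members of
    adjacent levels; everything irrelevant to the perspective drops out.
    """
    if perspective_id not in registry.perspectives:
        known = sorted(registry.perspectives)
        raise KeyError(f"unknown perspective {perspective_id!r}; "
                       f"known ids: {known}")
    p = registry[perspective_id]
    entries = assignments.for_perspective(perspective_id)
    level_of = dict(entries)
    members = set(level_of)

    sub = AssertionSet(aset.entities[eid] for eid in sorted(members))
    relation = p.criterion.relation
    for a in aset.by_predicate(relation) if relation in PREDICATES else ():
        if (a.subject in members and a.object in members
                and abs(level_of[a.subject] - level_of[a.object]) == 1):
            sub.add_assertion(a)
    return sub
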