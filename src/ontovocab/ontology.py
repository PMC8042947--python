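"""Ontology loading and cross-ontology lookup structures.

Classes from OWL (RDF/XML) and OBO documents are reduced to flat
:class:`TermRecord` objects carrying the six conventional labelling
annotation properties (``rdfs:label``, ``skos:altLabel``,
``oboInOwl:hasExactSynonym`` / ``hasNarrowSynonym`` / ``hasBroadSynonym``
and ``IAO:0000118``).  ``hasRelatedSynonym`` is deliberately excluded:
related-scope synonyms are too imprecise for vocabulary expansion.

Two repository-wide structures feed the expansion algorithm:

* a :class:`LabelIndex` mapping every normalised label or synonym to the
  classes that carry it (the lexical-matching substrate), and
* an :class:`EquivalenceGraph` partitioning all loaded classes into
  equivalence components, the transitive closure of shared-IRI identity
  and asserted named-class equivalence axioms (the equivalency-query
  substrate; no description-logic reasoning is performed).
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import obonet
import rdflib
from rdflib import OWL, RDF, RDFS

__all__ = [
    "TermRecord",
    "OntologyDocument",
    "LabelIndex",
    "EquivalenceGraph",
    "Repository",
    "OntologyLoadError",
    "UnlabelledClassError",
    "normalize_label",
    "load_ontology",
    "extract_first_label",
    "build_label_index",
    "build_equivalence_graph",
    "subclasses_of",
    "write_term_records",
    "read_term_records",
]

#: synonym scopes retained at load time; 'related' is excluded on purpose
SYNONYM_SCOPES = ("exact", "narrow", "broad", "alt", "alternative_term")

OBO_PURL = "http://purl.obolibrary.org/obo/"

_OBOINOWL = "http://www.geneontology.org/formats/oboInOwl#"
_SKOS_ALT = rdflib.URIRef("http://www.w3.org/2004/02/skos/core#altLabel")
_IAO_ALT = rdflib.URIRef(OBO_PURL + "IAO_0000118")
_SYNONYM_PREDICATES = {
    rdflib.URIRef(_OBOINOWL + "hasExactSynonym"): "exact",
    rdflib.URIRef(_OBOINOWL + "hasNarrowSynonym"): "narrow",
    rdflib.URIRef(_OBOINOWL + "hasBroadSynonym"): "broad",
    _SKOS_ALT: "alt",
    _IAO_ALT: "alternative_term",
}

_WS = re.compile(r"\s+")


class OntologyLoadError(RuntimeError):
    """An ontology document could not be parsed."""


class UnlabelledClassError(ValueError):
    """Raised when a first label is requested for a class with no labels."""


def normalize_label(text: str, strict: bool = False) -> str:
    """Normalise a label for exact matching.

    Default mode lowercases, collapses internal whitespace and strips
    surrounding whitespace — capitalisation conventions differ across
    ontologies.  ``strict=True`` keeps byte equality.
    """
    if strict:
        return text
    return _WS.sub(" ", text).strip().lower()


@dataclass(frozen=True)
class TermRecord:
    """One ontology class with its labelling metadata."""

    iri: str
    ontology_id: str
    labels: tuple[str, ...] = ()
    synonyms: tuple[tuple[str, str], ...] = ()  # (text, scope)
    obsolete: bool = False

    def __post_init__(self) -> None:
        for text, scope in self.synonyms:
            if not text:
                raise ValueError(f"empty synonym text on {self.iri}")
            if scope not in SYNONYM_SCOPES:
                raise ValueError(f"unknown synonym scope {scope!r} on {self.iri}")

    @property
    def first_label(self) -> str:
        return extract_first_label(self)

    def all_label_texts(self) -> list[str]:
        """Labels followed by synonym texts, in asserted order."""
        return list(self.labels) + [t for t, _ in self.synonyms]


def extract_first_label(record: TermRecord) -> str:
    """The class's primary label.

    A unique primary-label value is returned as-is; with several values
    the lexicographically smallest wins, since neither OWL nor the OBO
    flat-file format imposes a reliable label order across parsers.
    """
    if not record.labels:
        raise UnlabelledClassError(f"class {record.iri} has no labels")
    if len(record.labels) == 1:
        return record.labels[0]
    return min(record.labels)


@dataclass
class OntologyDocument:
    """A loaded ontology: term records plus its structural axioms."""

    ontology_id: str
    source_path: str
    classes: dict[str, TermRecord] = field(default_factory=dict)
    equivalence_axioms: list[tuple[str, str]] = field(default_factory=list)
    subclass_edges: list[tuple[str, str]] = field(default_factory=list)  # (child, parent)
    n_anonymous_equivalences_dropped: int = 0

    def record(self, iri: str) -> TermRecord:
        return self.classes[iri]

    def __iter__(self) -> Iterable[TermRecord]:
        return iter(self.classes.values())


def curie_to_iri(curie: str) -> str:
    """Map an OBO-style CURIE (``HP:0000822``) onto its OBO PURL."""
    if curie.startswith("http://") or curie.startswith("https://"):
        return curie
    if ":" in curie:
        prefix, local = curie.split(":", 1)
        return f"{OBO_PURL}{prefix}_{local}"
    return f"{OBO_PURL}{curie}"


_OBO_SYNONYM = re.compile(r'^"(?P<text>(?:[^"\\]|\\.)*)"\s*(?P<scope>[A-Z_]*)')

_OBO_SCOPE_MAP = {
    "EXACT": "exact",
    "NARROW": "narrow",
    "BROAD": "broad",
    "": "exact",  # OBO default scope is RELATED; unscoped synonyms are rare
    # and fixtures always scope them, but 'exact' is the safe retention choice
}


def _parse_obo_synonym(raw: str) -> tuple[str, str] | None:
    m = _OBO_SYNONYM.match(raw.strip())
    if m is None:
        return None
    scope = m.group("scope")
    if scope == "RELATED":
        return None  # excluded: too imprecise
    mapped = _OBO_SCOPE_MAP.get(scope)
    if mapped is None:
        return None
    text = m.group("text").replace('\\"', '"')
    return (text, mapped)


def _load_obo(path: Path, ontology_id: str) -> OntologyDocument:
    try:
        graph = obonet.read_obo(str(path), ignore_obsolete=False)
    except Exception as exc:  # pragma: no cover - message formatting only
        raise OntologyLoadError(f"cannot parse OBO file {path}: {exc}") from exc

    doc = OntologyDocument(ontology_id=ontology_id, source_path=str(path))
    for node, data in sorted(graph.nodes(data=True)):
        iri = curie_to_iri(node)
        labels = tuple([data["name"]] if "name" in data else [])
        synonyms = []
        for raw in data.get("synonym", []):
            parsed = _parse_obo_synonym(raw)
            if parsed is not None:
                synonyms.append(parsed)
        obsolete = str(data.get("is_obsolete", "false")).lower() == "true"
        doc.classes[iri] = TermRecord(
            iri=iri,
            ontology_id=ontology_id,
            labels=labels,
            synonyms=tuple(synonyms),
            obsolete=obsolete,
        )
        for target in data.get("equivalent_to", []):
            doc.equivalence_axioms.append((iri, curie_to_iri(target)))
        for parent in data.get("is_a", []):
            doc.subclass_edges.append((iri, curie_to_iri(parent)))
    return doc


def _load_owl_rdfxml(path: Path, ontology_id: str) -> OntologyDocument:
    g = rdflib.Graph()
    try:
        g.parse(str(path), format="xml")
    except Exception as exc:
        raise OntologyLoadError(f"cannot parse RDF/XML file {path}: {exc}") from exc

    doc = OntologyDocument(ontology_id=ontology_id, source_path=str(path))
    named = [c for c in g.subjects(RDF.type, OWL.Class) if isinstance(c, rdflib.URIRef)]
    deprecated = rdflib.URIRef("http://www.w3.org/2002/07/owl#deprecated")
    for cls in sorted(set(named)):
        labels = sorted(str(o) for o in g.objects(cls, RDFS.label))
        synonyms: list[tuple[str, str]] = []
        for pred, scope in _SYNONYM_PREDICATES.items():
            for o in sorted(g.objects(cls, pred)):
                synonyms.append((str(o), scope))
        obsolete = any(
            str(o).lower() == "true" for o in g.objects(cls, deprecated)
        )
        doc.classes[str(cls)] = TermRecord(
            iri=str(cls),
            ontology_id=ontology_id,
            labels=tuple(labels),
            synonyms=tuple(synonyms),
            obsolete=obsolete,
        )
        for o in g.objects(cls, RDFS.subClassOf):
            if isinstance(o, rdflib.URIRef):
                doc.subclass_edges.append((str(cls), str(o)))
        for o in g.objects(cls, OWL.equivalentClass):
            if isinstance(o, rdflib.URIRef):
                doc.equivalence_axioms.append((str(cls), str(o)))
            else:
                # anonymous class expression (logical definition): ignored,
                # DL reasoning over them is out of scope
                doc.n_anonymous_equivalences_dropped += 1
    doc.subclass_edges.sort()
    doc.equivalence_axioms.sort()
    return doc


def load_ontology(path: str | Path, format: str, ontology_id: str) -> OntologyDocument:
    """Load one ontology document.

    Parameters
    ----------
    path
        File to read.
    format
        ``"obo"`` or ``"owl_rdfxml"``.
    ontology_id
        Short name of the ontology (e.g. ``"DOID"``, ``"HP"``) used for
        provenance and blocklist filtering.
    """
    if format not in ("obo", "owl_rdfxml"):
        raise ValueError(f"unknown ontology format {format!r}")
    path = Path(path)
    if not path.exists():
        raise OntologyLoadError(f"ontology file not found: {path}")
    if format == "obo":
        return _load_obo(path, ontology_id)
    return _load_owl_rdfxml(path, ontology_id)


class LabelIndex:
    """Normalised label/synonym → set of ``(ontology_id, iri)``.

    The same normaliser is applied at build and query time; obsolete
    classes are not indexed.
    """

    def __init__(self, strict: bool = False) -> None:
        self.strict = strict
        self._index: dict[str, set[tuple[str, str]]] = {}

    def add(self, text: str, ontology_id: str, iri: str) -> None:
        key = normalize_label(text, strict=self.strict)
        self._index.setdefault(key, set()).add((ontology_id, iri))

    def lookup(self, text: str) -> set[tuple[str, str]]:
        return set(self._index.get(normalize_label(text, strict=self.strict), ()))

    def __len__(self) -> int:
        return len(self._index)

    def keys(self) -> Iterable[str]:
        return self._index.keys()


def build_label_index(
    documents: Iterable[OntologyDocument], strict: bool = False
) -> LabelIndex:
    """Index every label and synonym of every non-obsolete loaded class."""
    index = LabelIndex(strict=strict)
    for doc in documents:
        for record in doc:
            if record.obsolete:
                continue
            for text in record.all_label_texts():
                index.add(text, record.ontology_id, record.iri)
    return index


class EquivalenceGraph:
    """Partition of loaded classes into equivalence components.

    Nodes are ``(ontology_id, iri)`` occurrences.  Edges join (i) records
    sharing an IRI across documents — classes with the same IRI are the
    same class — and (ii) records linked by an asserted named-class
    equivalence axiom.  Components are the connected components of that
    graph, i.e. the reflexive-symmetric-transitive closure.
    """

    def __init__(self, component_of: Mapping[tuple[str, str], int]) -> None:
        self._component_of = dict(component_of)
        self._members: dict[int, set[tuple[str, str]]] = {}
        for node, comp in self._component_of.items():
            self._members.setdefault(comp, set()).add(node)

    def component_id(self, ontology_id: str, iri: str) -> int:
        return self._component_of[(ontology_id, iri)]

    def members(self, ontology_id: str, iri: str) -> set[tuple[str, str]]:
        """All occurrences equivalent to the given one, including itself."""
        comp = self._component_of.get((ontology_id, iri))
        if comp is None:
            return {(ontology_id, iri)}
        return set(self._members[comp])

    def __contains__(self, node: tuple[str, str]) -> bool:
        return node in self._component_of

    @property
    def n_components(self) -> int:
        return len(self._members)


def build_equivalence_graph(documents: Iterable[OntologyDocument]) -> EquivalenceGraph:
    """Connected-component closure of shared-IRI identity and asserted axioms."""
    docs = list(documents)
    g: nx.Graph = nx.Graph()
    by_iri: dict[str, list[tuple[str, str]]] = {}
    for doc in docs:
        for record in doc:
            if record.obsolete:
                continue
            node = (record.ontology_id, record.iri)
            g.add_node(node)
            by_iri.setdefault(record.iri, []).append(node)
    # same IRI in different documents → same class
    for nodes in by_iri.values():
        for a, b in zip(nodes, nodes[1:]):
            g.add_edge(a, b)
    # asserted named-class equivalences link every occurrence of both IRIs
    for doc in docs:
        for iri_a, iri_b in doc.equivalence_axioms:
            occ_a = by_iri.get(iri_a, [])
            occ_b = by_iri.get(iri_b, [])
            for a in occ_a:
                for b in occ_b:
                    g.add_edge(a, b)
    component_of: dict[tuple[str, str], int] = {}
    for comp_id, comp in enumerate(sorted(nx.connected_components(g), key=min)):
        for node in comp:
            component_of[node] = comp_id
    return EquivalenceGraph(component_of)


def subclasses_of(document: OntologyDocument, root_iri: str) -> set[str]:
    """Transitive non-obsolete subclasses of ``root_iri`` (root excluded)."""
    if root_iri not in document.classes:
        raise KeyError(f"root IRI {root_iri} not in ontology {document.ontology_id}")
    children: dict[str, list[str]] = {}
    for child, parent in document.subclass_edges:
        children.setdefault(parent, []).append(child)
    seen: set[str] = set()
    stack = [root_iri]
    while stack:
        for child in children.get(stack.pop(), ()):
            if child not in seen:
                seen.add(child)
                stack.append(child)
    return {
        iri
        for iri in seen
        if iri in document.classes and not document.classes[iri].obsolete
    }


class Repository:
    """A set of loaded ontologies plus the lookup structures over them."""

    def __init__(self, documents: Iterable[OntologyDocument], strict_labels: bool = False):
        self.documents = list(documents)
        self.strict_labels = strict_labels
        self._records: dict[tuple[str, str], TermRecord] = {}
        for doc in self.documents:
            for record in doc:
                self._records[(record.ontology_id, record.iri)] = record
        self._index: LabelIndex | None = None
        self._graph: EquivalenceGraph | None = None

    @classmethod
    def load(
        cls,
        paths: Iterable[tuple[str | Path, str, str]],
        strict_labels: bool = False,
    ) -> "Repository":
        """Load from ``(path, format, ontology_id)`` triples."""
        return cls(
            [load_ontology(p, fmt, oid) for p, fmt, oid in paths],
            strict_labels=strict_labels,
        )

    @property
    def label_index(self) -> LabelIndex:
        if self._index is None:
            self._index = build_label_index(self.documents, strict=self.strict_labels)
        return self._index

    @property
    def equivalence_graph(self) -> EquivalenceGraph:
        if self._graph is None:
            self._graph = build_equivalence_graph(self.documents)
        return self._graph

    def record(self, ontology_id: str, iri: str) -> TermRecord:
        return self._records[(ontology_id, iri)]

    def find_by_iri(self, iri: str) -> list[TermRecord]:
        return [r for (oid, i), r in sorted(self._records.items()) if i == iri]

    def __iter__(self) -> Iterable[TermRecord]:
        return iter(self._records.values())


TSV_COLUMNS = ["ontology_id", "iri", "first_label", "label", "property_scope"]


def write_term_records(documents: Iterable[OntologyDocument], path: str | Path) -> None:
    """Write loaded term records to TSV, one row per label/synonym."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(TSV_COLUMNS)
        for doc in documents:
            for record in doc:
                if not record.labels and not record.synonyms:
                    continue
                first = record.labels and extract_first_label(record) or ""
                for text in record.labels:
                    writer.writerow([record.ontology_id, record.iri, first, text, "label"])
                for text, scope in record.synonyms:
                    writer.writerow([record.ontology_id, record.iri, first, text, scope])


def read_term_records(path: str | Path) -> list[TermRecord]:
    """Re-read a term-record TSV written by :func:`write_term_records`."""
    rows: dict[tuple[str, str], dict] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            key = (row["ontology_id"], row["iri"])
            entry = rows.setdefault(key, {"labels": [], "synonyms": []})
            if row["property_scope"] == "label":
                entry["labels"].append(row["label"])
            else:
                entry["synonyms"].append((row["label"], row["property_scope"]))
    return [
        TermRecord(
            iri=iri,
            ontology_id=oid,
            labels=tuple(entry["labels"]),
            synonyms=tuple(entry["synonyms"]),
        )
        for (oid, iri), entry in rows.items()
    ]
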