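"""Loading OWL documents and extracting the facts the checks consume.

Documents are read with rdflib (RDF/XML or Turtle) and distilled into an
:class:`OntologyDocument`: the ontology IRI, version IRI, ontology-level
annotations, and one :class:`EntityRecord` per declared term with its
category, labels, textual definitions and deprecation flag.  No reasoning
and no import resolution — each document is checked as given.
"""

from __future__ import annotations

import datetime
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import BinaryIO, Union

import rdflib
from rdflib import RDF, RDFS, OWL, Literal, URIRef
from rdflib.namespace import DCTERMS

__all__ = [
    "DEFINITION_PROPERTY",
    "EntityCategory",
    "EntityRecord",
    "FormatError",
    "OntologyDocument",
    "get_license_annotations",
    "load_ontology",
    "parse_version_date",
]

# OBO convention annotation property for textual definitions (IAO "definition").
DEFINITION_PROPERTY = URIRef("http://purl.obolibrary.org/obo/IAO_0000115")

_DC_ELEMENTS = "http://purl.org/dc/elements/1.1/"
# Near-miss properties under which license info is sometimes (wrongly) placed.
LICENSE_NEAR_MISS_PROPERTIES = (
    URIRef(_DC_ELEMENTS + "license"),
    URIRef(_DC_ELEMENTS + "rights"),
    URIRef(str(DCTERMS.rights)),
)


class EntityCategory(str, Enum):
    CLASS = "class"
    OBJECT_PROPERTY = "object_property"
    DATA_PROPERTY = "data_property"
    ANNOTATION_PROPERTY = "annotation_property"
    NAMED_INDIVIDUAL = "named_individual"


@dataclass
class EntityRecord:
    """One term: IRI, category, labels, definitions, deprecation flag."""

    iri: str
    category: EntityCategory
    labels: list[str] = field(default_factory=list)
    definitions: list[str] = field(default_factory=list)
    deprecated: bool = False


@dataclass
class FormatError:
    """A document that could not be parsed as RDF/XML or Turtle."""

    message: str
    byte_offset_or_line: int | None = None


@dataclass
class OntologyDocument:
    """Parsed ontology facts, plus the underlying graph for serialization."""

    ontology_iri: str | None = None
    version_iri: str | None = None
    annotations: dict[str, list[str]] = field(default_factory=dict)
    entities: list[EntityRecord] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    graph: rdflib.Graph | None = None

    def entity(self, iri: str) -> EntityRecord | None:
        for record in self.entities:
            if record.iri == iri:
                return record
        return None


_CATEGORY_BY_TYPE = {
    OWL.Class: EntityCategory.CLASS,
    OWL.ObjectProperty: EntityCategory.OBJECT_PROPERTY,
    OWL.DatatypeProperty: EntityCategory.DATA_PROPERTY,
    OWL.AnnotationProperty: EntityCategory.ANNOTATION_PROPERTY,
    OWL.NamedIndividual: EntityCategory.NAMED_INDIVIDUAL,
}

# Category precedence when a subject carries several type declarations.
_CATEGORY_ORDER = [
    OWL.ObjectProperty,
    OWL.DatatypeProperty,
    OWL.AnnotationProperty,
    OWL.NamedIndividual,
    OWL.Class,
]


def _sniff_format(data: bytes) -> str:
    head = data.lstrip()[:512]
    if head.startswith(b"<?xml") or head.startswith(b"<rdf:RDF") or head.startswith(b"<RDF"):
        return "xml"
    return "turtle"


def load_ontology(
    source: Union[str, Path, bytes, BinaryIO],
    format_hint: str | None = None,
) -> OntologyDocument | FormatError:
    """Parse an ontology document into fact records.

    ``format_hint`` may be ``"rdfxml"`` or ``"turtle"``; when omitted the
    serialization is sniffed from the content.  A document that cannot be
    parsed yields a :class:`FormatError` value (which feeds the common
    format check directly); an unreadable path raises ``OSError``.
    """
    if isinstance(source, (str, Path)):
        data = Path(source).read_bytes()
    elif isinstance(source, bytes):
        data = source
    else:
        data = source.read()

    fmt = {"rdfxml": "xml", "turtle": "turtle", None: None}.get(format_hint, format_hint)
    if fmt is None:
        fmt = _sniff_format(data)

    graph = rdflib.Graph()
    try:
        graph.parse(data=data, format=fmt)
    except Exception as exc:  # rdflib raises format-specific parse errors
        line = getattr(exc, "lines", None) or getattr(exc, "line", None)
        return FormatError(message=f"{type(exc).__name__}: {exc}", byte_offset_or_line=line)

    doc = OntologyDocument(graph=graph)

    ontology_nodes = sorted(
        (s for s in graph.subjects(RDF.type, OWL.Ontology) if isinstance(s, URIRef)),
        key=str,
    )
    if ontology_nodes:
        doc.ontology_iri = str(ontology_nodes[0])
        if len(ontology_nodes) > 1:
            doc.warnings.append(
                f"multiple ontology headers; keeping {doc.ontology_iri}"
            )
        version_iris = sorted(
            str(o) for o in graph.objects(ontology_nodes[0], OWL.versionIRI)
        )
        if version_iris:
            doc.version_iri = version_iris[0]
            if len(version_iris) > 1:
                doc.warnings.append(
                    f"multiple version IRIs; keeping {doc.version_iri}"
                )
        for prop, value in graph.predicate_objects(ontology_nodes[0]):
            if prop in (RDF.type, OWL.versionIRI):
                continue
            doc.annotations.setdefault(str(prop), []).append(str(value))
        for values in doc.annotations.values():
            values.sort()

    # Entities: explicit declarations, plus subjects of label/definition
    # annotations (defaulting to class).  Blank nodes are never entities.
    categories: dict[URIRef, EntityCategory] = {}
    for type_iri in _CATEGORY_ORDER:
        for subject in graph.subjects(RDF.type, type_iri):
            if isinstance(subject, URIRef) and subject not in categories:
                categories[subject] = _CATEGORY_BY_TYPE[type_iri]
    for prop in (RDFS.label, DEFINITION_PROPERTY):
        for subject in graph.subjects(prop, None):
            if isinstance(subject, URIRef) and subject not in categories:
                if subject not in set(ontology_nodes):
                    categories[subject] = EntityCategory.CLASS

    for subject in sorted(categories, key=str):
        labels = sorted(str(o) for o in graph.objects(subject, RDFS.label))
        definitions = sorted(str(o) for o in graph.objects(subject, DEFINITION_PROPERTY))
        deprecated = any(
            isinstance(o, Literal) and o.toPython() is True
            for o in graph.objects(subject, OWL.deprecated)
        )
        doc.entities.append(
            EntityRecord(
                iri=str(subject),
                category=categories[subject],
                labels=labels,
                definitions=definitions,
                deprecated=deprecated,
            )
        )
    return doc


def get_license_annotations(
    doc: OntologyDocument,
) -> tuple[list[str], list[str]]:
    """License values on the ontology header.

    Returns ``(candidates, wrong_property_uses)``: values of the canonical
    dcterms license property, and the IRIs of near-miss properties (legacy
    Dublin Core elements license/rights) that carry license-like values.
    """
    candidates = list(doc.annotations.get(str(DCTERMS.license), []))
    wrong: list[str] = []
    for prop in LICENSE_NEAR_MISS_PROPERTIES:
        if doc.annotations.get(str(prop)):
            wrong.append(str(prop))
    return candidates, wrong


_DATE_SEGMENT = re.compile(r"(?:^|/)(\d{4})-(\d{2})-(\d{2})(?:/|$)")


def parse_version_date(version_iri: str) -> datetime.date | None:
    """Extract a release date from a version IRI.

    Returns the date iff the IRI contains a path segment of the form
    YYYY-MM-DD that is a real calendar date; otherwise ``None`` (e.g.
    2021-02-30 is rejected).
    """
    if not version_iri:
        return None
    match = _DATE_SEGMENT.search(version_iri)
    if not match:
        return None
    year, month, day = (int(g) for g in match.groups())
    try:
        return datetime.date(year, month, day)
    except ValueError:
        return None
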