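"""Deterministic test-fixture generator.

Produces a registry record (YAML) plus a matching ontology document
(Turtle), either clean or carrying exactly the named seeded violations,
together with the expected per-principle outcome map.  Running the full
check battery over a generated fixture and comparing against its expected
map is the central self-consistency oracle of the test suite: every
detectable fault kind is exercised offline, with no network and no
external downloads.
"""

from __future__ import annotations

import datetime
import random
from dataclasses import dataclass, field

import yaml

from .checks import CheckContext, CheckStatus, load_ro_index
from .registry import parse_registry

__all__ = [
    "FIXTURE_TODAY",
    "FixtureSpec",
    "VIOLATION_KINDS",
    "generate_fixture",
    "make_context",
    "standard_peers_yaml",
    "to_rdfxml",
    "violation_catalog",
]

OBO = "http://purl.obolibrary.org/obo/"
CC_BY_4 = "https://creativecommons.org/licenses/by/4.0/"
CC0 = "https://creativecommons.org/publicdomain/zero/1.0/"
RO_DEVELOPS_FROM = OBO + "RO_0002202"
IAO_DEFINITION = OBO + "IAO_0000115"

#: Reference date used by fixtures so maintenance checks are reproducible.
FIXTURE_TODAY = datetime.date(2021, 5, 15)

_CONTACTS = [
    ("Alex Curator", "alex.curator@example.org"),
    ("Sam Maintainer", "sam.maintainer@example.org"),
    ("Robin Steward", "robin.steward@example.org"),
]

# kind -> (target principle, expected status overrides, description).
# Most kinds perturb exactly one cell; a malformed file takes down every
# ontology-dependent check, and the two version-IRI kinds couple FP4 with
# FP16 (both read the version IRI).
VIOLATION_KINDS: dict[str, tuple[str, dict[str, CheckStatus], str]] = {
    "license_missing": ("FP1", {"FP1": CheckStatus.ERROR}, "registry record has no license entry"),
    "license_not_accepted": ("FP1", {"FP1": CheckStatus.ERROR}, "license is not CC0/CC BY"),
    "license_mismatch": ("FP1", {"FP1": CheckStatus.ERROR}, "ontology and registry licenses differ"),
    "wrong_license_property": ("FP1", {"FP1": CheckStatus.ERROR}, "license under a legacy Dublin Core property"),
    "malformed_file": (
        "FP2",
        {
            pid: CheckStatus.ERROR
            for pid in ("FP1", "FP2", "FP3", "FP4", "FP6", "FP7", "FP12", "FP16")
        },
        "ontology file truncated mid-document",
    ),
    "iri_no_underscore": ("FP3", {"FP3": CheckStatus.ERROR}, "term IRI lacks the underscore after the prefix"),
    "iri_nonnumeric": ("FP3", {"FP3": CheckStatus.ERROR}, "term IRI has a non-numeric local id"),
    "version_iri_absent": (
        "FP4",
        {"FP4": CheckStatus.ERROR, "FP16": CheckStatus.WARN},
        "ontology header has no version IRI",
    ),
    "version_iri_nondate": (
        "FP4",
        {"FP4": CheckStatus.INFO, "FP16": CheckStatus.WARN},
        "version IRI is not in YYYY-MM-DD form",
    ),
    "domain_missing": ("FP5", {"FP5": CheckStatus.ERROR}, "registry record has no domain tag"),
    "domain_shared": ("FP5", {"FP5": CheckStatus.INFO}, "domain tag shared with a peer ontology"),
    "def_missing": ("FP6", {"FP6": CheckStatus.WARN}, "a live class has no textual definition"),
    "def_duplicate": ("FP6", {"FP6": CheckStatus.ERROR}, "two classes share an identical definition"),
    "def_multiple": ("FP6", {"FP6": CheckStatus.ERROR}, "a class carries two distinct definitions"),
    "nonro_property": ("FP7", {"FP7": CheckStatus.WARN}, "object property not reused from RO"),
    "homepage_missing": ("FP8", {"FP8": CheckStatus.ERROR}, "registry record has no homepage"),
    "homepage_404": ("FP8", {"FP8": CheckStatus.ERROR}, "homepage does not resolve (HTTP 404)"),
    "usages_empty": ("FP9", {"FP9": CheckStatus.ERROR}, "registry record documents no usages"),
    "contact_malformed": ("FP11", {"FP11": CheckStatus.ERROR}, "contact label is an email address"),
    "label_missing": ("FP12", {"FP12": CheckStatus.ERROR}, "a live class has no rdfs:label"),
    "label_duplicate": ("FP12", {"FP12": CheckStatus.ERROR}, "two classes share an identical label"),
    "label_multiple": ("FP12", {"FP12": CheckStatus.ERROR}, "a class carries two labels"),
    "stale_version_date": ("FP16", {"FP16": CheckStatus.ERROR}, "dated release is four years old"),
    "tracker_missing": ("FP20", {"FP20": CheckStatus.ERROR}, "registry record has no tracker URL"),
}


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one generated (registry record, ontology) pair."""

    idspace: str = "exf"
    n_classes: int = 5
    n_object_properties: int = 1
    n_deprecated: int = 1
    seed: int = 42
    violations: tuple[str, ...] = ()

    def __post_init__(self):
        if self.n_deprecated > self.n_classes:
            raise ValueError("n_deprecated cannot exceed n_classes")
        if self.n_classes - self.n_deprecated < 2:
            raise ValueError("need at least 2 live classes for duplicate seeds")
        unknown = set(self.violations) - set(VIOLATION_KINDS)
        if unknown:
            raise ValueError(f"unknown violation kinds: {sorted(unknown)}")
        if "malformed_file" in self.violations and len(self.violations) > 1:
            raise ValueError("malformed_file is exclusive of other seeded violations")


def violation_catalog() -> list[tuple[str, str, str]]:
    """(kind, target principle, description) for every seedable fault."""
    return [(kind, tgt, desc) for kind, (tgt, _, desc) in VIOLATION_KINDS.items()]


def _clean_expected() -> dict[str, CheckStatus]:
    from .checks import PRINCIPLE_IDS

    expected = {pid: CheckStatus.PASS for pid in PRINCIPLE_IDS}
    expected["FP8"] = CheckStatus.INFO  # homepage not probed offline
    return expected


def standard_peers_yaml() -> str:
    """Two fixed active peer records (domains: anatomy, health) used as the
    comparison set for scope checks."""
    peers = []
    for pid, domain in (("aex", "anatomy"), ("hex", "health")):
        peers.append(
            {
                "id": pid,
                "title": f"{pid.upper()} Example Ontology",
                "homepage": f"https://example.org/{pid}",
                "contact": {"label": "Peer Curator", "email": "peer@example.org"},
                "description": f"Example peer ontology for the {domain} domain.",
                "license": {"label": "CC BY 4.0", "url": CC_BY_4},
                "products": [{"id": f"{pid}.owl"}],
                "activity_status": "active",
                "is_obsolete": False,
                "domain": domain,
                "usages": [{"user": f"https://example.org/{pid}-users"}],
                "tracker": f"https://example.org/{pid}/issues",
            }
        )
    return yaml.safe_dump({"ontologies": peers}, sort_keys=False)


def _registry_mapping(spec: FixtureSpec, rng: random.Random) -> dict:
    oid = spec.idspace.lower()
    label, email = _CONTACTS[rng.randrange(len(_CONTACTS))]
    record: dict = {
        "id": oid,
        "title": f"{spec.idspace.upper()} Example Ontology",
        "homepage": f"https://example.org/{oid}",
        "contact": {"label": label, "email": email},
        "description": "A generated ontology of example terms used to exercise principle checks.",
        "license": {"label": "CC BY 4.0", "url": CC_BY_4},
        "products": [{"id": f"{oid}.owl"}],
        "activity_status": "active",
        "is_obsolete": False,
        "domain": "example phenomena",
        "usages": [{"user": f"https://example.org/{oid}-users", "description": "Uses the ontology for annotation."}],
        "tracker": f"https://example.org/{oid}/issues",
    }
    seeds = set(spec.violations)
    if "license_missing" in seeds:
        del record["license"]
    if "license_not_accepted" in seeds:
        record["license"] = {"label": "GPL-3.0", "url": "https://www.gnu.org/licenses/gpl-3.0.html"}
    if "domain_missing" in seeds:
        del record["domain"]
    if "domain_shared" in seeds:
        record["domain"] = "anatomy"
    if "homepage_missing" in seeds:
        del record["homepage"]
    if "usages_empty" in seeds:
        record["usages"] = []
    if "contact_malformed" in seeds:
        record["contact"] = {"label": email, "email": email}
    if "tracker_missing" in seeds:
        del record["tracker"]
    return record


def _ttl_literal(text: str) -> str:
    return '"' + text.replace("\\", "\\\\").replace('"', '\\"') + '"'


def _ontology_turtle(spec: FixtureSpec, rng: random.Random) -> str:
    seeds = set(spec.violations)
    prefix = spec.idspace.upper()
    oid = spec.idspace.lower()
    ontology_iri = f"{OBO}{oid}.owl"

    version_date = FIXTURE_TODAY - datetime.timedelta(days=60)
    if "stale_version_date" in seeds:
        version_date = FIXTURE_TODAY.replace(year=FIXTURE_TODAY.year - 4)
    version_iri = f"{OBO}{oid}/{version_date.isoformat()}/{oid}.owl"
    if "version_iri_nondate" in seeds:
        version_iri = f"{OBO}{oid}/v1.2/{oid}.owl"

    license_url = CC0 if "license_mismatch" in seeds else CC_BY_4
    license_prop = (
        "dc:license" if "wrong_license_property" in seeds else "dcterms:license"
    )

    lines = [
        "@prefix owl: <http://www.w3.org/2002/07/owl#> .",
        "@prefix rdfs: <http://www.w3.org/2000/01/rdf-schema#> .",
        "@prefix xsd: <http://www.w3.org/2001/XMLSchema#> .",
        "@prefix dcterms: <http://purl.org/dc/terms/> .",
        "@prefix dc: <http://purl.org/dc/elements/1.1/> .",
        f"@prefix obo: <{OBO}> .",
        "",
        f"<{ontology_iri}> a owl:Ontology ;",
    ]
    if "version_iri_absent" not in seeds:
        lines.append(f"    owl:versionIRI <{version_iri}> ;")
    if "license_missing" in seeds:
        # the registry fault; the ontology keeps its annotation
        lines.append(f"    {license_prop} <{license_url}> ;")
    elif "license_not_accepted" in seeds:
        lines.append(f"    {license_prop} <https://www.gnu.org/licenses/gpl-3.0.html> ;")
    else:
        lines.append(f"    {license_prop} <{license_url}> ;")
    lines.append(
        f"    rdfs:comment {_ttl_literal('Generated example ontology ' + prefix)} ."
    )
    lines.append("")
    lines.append(f"<{IAO_DEFINITION}> a owl:AnnotationProperty ;")
    lines.append(f'    rdfs:label "definition" .')
    lines.append("")

    local_start = 1 + rng.randrange(9000)
    n_live = spec.n_classes - spec.n_deprecated
    for i in range(spec.n_classes):
        iri = f"obo:{prefix}_{local_start + i:07d}"
        term_label = f"example term {local_start + i}"
        definition = f"A generated example term number {local_start + i}."
        labels = [term_label]
        definitions = [definition]
        if i == 0:
            if "label_missing" in seeds:
                labels = []
            if "label_multiple" in seeds:
                labels.append(term_label + " (alternate)")
            if "def_missing" in seeds:
                definitions = []
            if "def_multiple" in seeds:
                definitions.append(definition + " Stated a second way.")
        if i == 1:
            if "label_duplicate" in seeds:
                labels = [f"example term {local_start}"]
            if "def_duplicate" in seeds:
                definitions = [f"A generated example term number {local_start}."]
        lines.append(f"{iri} a owl:Class ;")
        for lab in labels:
            lines.append(f"    rdfs:label {_ttl_literal(lab)} ;")
        for d in definitions:
            lines.append(f"    obo:IAO_0000115 {_ttl_literal(d)} ;")
        if i >= n_live:
            lines.append('    owl:deprecated "true"^^xsd:boolean ;')
        lines[-1] = lines[-1].rstrip(";").rstrip() + " ."
        lines.append("")

    # First object property reuses RO; any further ones are local.
    for j in range(spec.n_object_properties):
        if j == 0:
            lines.append(f"<{RO_DEVELOPS_FROM}> a owl:ObjectProperty ;")
            lines.append('    rdfs:label "develops from" ;')
            lines.append(
                f"    obo:IAO_0000115 {_ttl_literal('A developmental relation between continuants.')} ."
            )
        else:
            iri = f"obo:{prefix}_{8000000 + j:07d}"
            lines.append(f"{iri} a owl:ObjectProperty ;")
            lines.append(f"    rdfs:label {_ttl_literal(f'example relation {j}')} ;")
            lines.append(
                f"    obo:IAO_0000115 {_ttl_literal(f'A generated local relation number {j}.')} ."
            )
        lines.append("")

    if "iri_no_underscore" in seeds:
        lines += [
            f"obo:{prefix}{local_start + 9990:07d} a owl:Class ;",
            f"    rdfs:label {_ttl_literal('badly minted term')} ;",
            f"    obo:IAO_0000115 {_ttl_literal('A term whose IRI lacks the underscore.')} .",
            "",
        ]
    if "iri_nonnumeric" in seeds:
        lines += [
            f"obo:{prefix}_extra a owl:Class ;",
            f"    rdfs:label {_ttl_literal('alphabetic id term')} ;",
            f"    obo:IAO_0000115 {_ttl_literal('A term whose local id is not numeric.')} .",
            "",
        ]
    if "nonro_property" in seeds:
        lines += [
            "<http://example.org/relations#related_to> a owl:ObjectProperty ;",
            f"    rdfs:label {_ttl_literal('related to')} ;",
            f"    obo:IAO_0000115 {_ttl_literal('A home-grown relation not taken from RO.')} .",
            "",
        ]
    return "\n".join(lines)


def generate_fixture(spec: FixtureSpec) -> tuple[str, bytes, dict[str, CheckStatus]]:
    """Generate ``(registry YAML text, ontology bytes, expected status map)``.

    The same spec (including seed) always yields identical bytes.  The
    expected map describes the outcome of running the full battery under
    :func:`make_context` — all PASS for a clean spec (FP8 INFO offline),
    with the seeded kinds' cells overridden.
    """
    rng = random.Random(spec.seed)
    registry_text = yaml.safe_dump(_registry_mapping(spec, rng), sort_keys=False)
    turtle = _ontology_turtle(spec, rng)
    ontology_bytes = turtle.encode()
    if "malformed_file" in spec.violations:
        ontology_bytes = ontology_bytes[: max(20, len(ontology_bytes) * 2 // 3)]

    expected = _clean_expected()
    for kind in spec.violations:
        _, overrides, _ = VIOLATION_KINDS[kind]
        for pid, status in overrides.items():
            expected[pid] = max(expected[pid], status)
    return registry_text, ontology_bytes, expected


def make_context(spec: FixtureSpec, ro_index=None) -> CheckContext:
    """The evaluation context the expected map assumes: fixed reference
    date, the two standard peers, the shipped RO index, and a stubbed
    homepage prober (online only for the homepage_404 kind)."""
    online_probe = "homepage_404" in spec.violations

    def prober(url: str) -> int:
        return 404 if online_probe else 200

    return CheckContext(
        today=FIXTURE_TODAY,
        peers=parse_registry(standard_peers_yaml()),
        ro_index=ro_index if ro_index is not None else load_ro_index(),
        http_prober=prober,
        offline=not online_probe,
    )


def to_rdfxml(ontology_bytes: bytes) -> bytes:
    """Re-serialize a generated Turtle document as RDF/XML (to exercise the
    second reader)."""
    import rdflib

    graph = rdflib.Graph()
    graph.parse(data=ontology_bytes, format="turtle")
    return graph.serialize(format="xml").encode()
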