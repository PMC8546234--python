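"""The thirteen automatable OBO Foundry principle checks.

Each check maps a registry entry and/or a parsed ontology document to a
:class:`CheckResult` — a graded status (PASS/INFO/WARN/ERROR/NA), a list
of human-readable findings with fix suggestions, and violation counters.
:func:`evaluate_ontology` runs the full battery for one ontology and
aggregates a worst-of summary.

Principles covered (FP numbers follow the Foundry numbering): FP1 Open,
FP2 Common Format, FP3 URI/Identifier Space, FP4 Versioning, FP5 Scope,
FP6 Textual Definitions, FP7 Relations, FP8 Documentation, FP9 Documented
Plurality of Users, FP11 Locus of Authority, FP12 Naming Conventions,
FP16 Maintenance, FP20 Responsiveness.  FP10 (Commitment to
Collaboration) cannot be automated and never appears in any result.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field
from enum import IntEnum
from pathlib import Path
from typing import Callable, Mapping, Sequence

from dateutil.relativedelta import relativedelta

from .ontology import (
    EntityCategory,
    FormatError,
    OntologyDocument,
    get_license_annotations,
    parse_version_date,
)
from .registry import (
    ACCEPTED_LICENSES,
    ContactInfo,
    RegistryEntry,
    canonicalize_license_url,
)

__all__ = [
    "CheckContext",
    "CheckResult",
    "CheckStatus",
    "DashboardRow",
    "OBO_PURL_BASE",
    "PRINCIPLES",
    "PRINCIPLE_IDS",
    "ROIndex",
    "check_definitions",
    "check_documentation",
    "check_format",
    "check_maintenance",
    "check_naming",
    "check_open",
    "check_registry_presence",
    "check_relations",
    "check_scope",
    "check_uris",
    "check_versioning",
    "default_config",
    "evaluate_ontology",
    "load_ro_index",
    "summarize",
]

OBO_PURL_BASE = "http://purl.obolibrary.org/obo/"


class CheckStatus(IntEnum):
    """Graded check outcome; worst-of aggregation uses the integer order.

    NA marks checks that were not applicable (e.g. inactive ontologies)
    and is excluded from aggregation.
    """

    NA = -1
    PASS = 0
    INFO = 1
    WARN = 2
    ERROR = 3

    def __str__(self) -> str:  # renders as "PASS" etc. in reports
        return self.name


#: (principle id, short name, documentation URL) in fixed column order.
PRINCIPLES: list[tuple[str, str, str]] = [
    ("FP1", "Open", "http://obofoundry.org/principles/fp-001-open.html"),
    ("FP2", "Common Format", "http://obofoundry.org/principles/fp-002-format.html"),
    ("FP3", "URI/Identifier Space", "http://obofoundry.org/principles/fp-003-uris.html"),
    ("FP4", "Versioning", "http://obofoundry.org/principles/fp-004-versioning.html"),
    ("FP5", "Scope", "http://obofoundry.org/principles/fp-005-delineated-content.html"),
    ("FP6", "Textual Definitions", "http://obofoundry.org/principles/fp-006-textual-definitions.html"),
    ("FP7", "Relations", "http://obofoundry.org/principles/fp-007-relations.html"),
    ("FP8", "Documentation", "http://obofoundry.org/principles/fp-008-documented.html"),
    ("FP9", "Documented Plurality of Users", "http://obofoundry.org/principles/fp-009-users.html"),
    ("FP11", "Locus of Authority", "http://obofoundry.org/principles/fp-011-locus-of-authority.html"),
    ("FP12", "Naming Conventions", "http://obofoundry.org/principles/fp-012-naming-conventions.html"),
    ("FP16", "Maintenance", "http://obofoundry.org/principles/fp-016-maintenance.html"),
    ("FP20", "Responsiveness", "http://obofoundry.org/principles/fp-020-responsiveness.html"),
]

PRINCIPLE_IDS: list[str] = [pid for pid, _, _ in PRINCIPLES]
PRINCIPLE_NAMES: dict[str, str] = {pid: name for pid, name, _ in PRINCIPLES}
PRINCIPLE_DOCS: dict[str, str] = {pid: url for pid, _, url in PRINCIPLES}


@dataclass
class CheckResult:
    """Outcome of one principle check for one ontology."""

    principle_id: str
    status: CheckStatus
    messages: list[str] = field(default_factory=list)
    metrics: dict[str, int] = field(default_factory=dict)


@dataclass
class DashboardRow:
    """One ontology's full battery of check results plus summary."""

    ontology_id: str
    results: dict[str, CheckResult]
    summary: CheckStatus


@dataclass(frozen=True)
class ROIndex:
    """Relations Ontology property index: IRIs plus a label lookup."""

    iris: frozenset[str]
    labels: Mapping[str, str]  # lowercase label -> IRI

    def __post_init__(self):
        missing = set(self.labels.values()) - set(self.iris)
        if missing:
            raise ValueError(f"labels map to IRIs not in the index: {missing}")


def load_ro_index(path: str | Path | None = None) -> ROIndex:
    """Load the two-column (IRI, label) tab-separated RO property index.

    Defaults to the curated subset shipped with the package.
    """
    if path is None:
        path = Path(__file__).parent / "data" / "ro_index.tsv"
    iris: set[str] = set()
    labels: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        iri, _, label = line.partition("\t")
        iris.add(iri)
        if label:
            labels[label.strip().lower()] = iri
    return ROIndex(iris=frozenset(iris), labels=labels)


def default_config() -> dict:
    """Default severity map and maintenance thresholds (all overridable)."""
    return {
        "def_missing": CheckStatus.WARN,
        "def_multiple": CheckStatus.ERROR,
        "def_duplicate": CheckStatus.ERROR,
        "label_missing": CheckStatus.ERROR,
        "label_multiple": CheckStatus.ERROR,
        "label_duplicate": CheckStatus.ERROR,
        "maintenance_warn_years": 2,
        "maintenance_error_years": 3,
    }


@dataclass
class CheckContext:
    """Shared evaluation context: clock, peers, RO index, HTTP prober."""

    today: datetime.date
    peers: Sequence[RegistryEntry] = ()
    ro_index: ROIndex | None = None
    http_prober: Callable[[str], int] | None = None
    config: dict = field(default_factory=default_config)
    offline: bool = True


def summarize(results: Mapping[str, CheckResult]) -> CheckStatus:
    """Worst-of aggregation over non-NA statuses (NA when nothing ran)."""
    statuses = [r.status for r in results.values() if r.status is not CheckStatus.NA]
    return max(statuses, default=CheckStatus.NA)


# ---------------------------------------------------------------------------
# FP1 Open


def check_open(entry: RegistryEntry, doc: OntologyDocument | None) -> CheckResult:
    """FP1: the license must be CC0 1.0 or CC BY 3.0/4.0, declared both in
    the registry (label + URL) and in the ontology under dcterms:license,
    and the two declarations must agree."""
    messages: list[str] = []
    status = CheckStatus.PASS
    registry_canonical: str | None = None

    lic = entry.license
    if lic is None or not lic.url or not lic.label:
        status = CheckStatus.ERROR
        messages.append(
            "registry license entry is missing a label and/or URL; "
            "add a 'license' record with both"
        )
    else:
        try:
            registry_canonical = canonicalize_license_url(lic.url)
        except ValueError:
            status = CheckStatus.ERROR
            messages.append(f"registry license url {lic.url!r} is not a URL")
        if registry_canonical is not None and registry_canonical not in ACCEPTED_LICENSES:
            status = CheckStatus.ERROR
            registry_canonical = None
            messages.append(
                f"license {lic.url} is not an accepted open license; "
                "use CC0 1.0, CC BY 3.0 or CC BY 4.0"
            )

    if doc is None:
        status = CheckStatus.ERROR
        messages.append(
            "license annotation not found: ontology document unavailable"
        )
        return CheckResult("FP1", status, messages, {"wrong_property": 0})

    candidates, wrong_property = get_license_annotations(doc)
    if len(candidates) == 0:
        status = CheckStatus.ERROR
        messages.append(
            "license annotation not found: add a dcterms:license annotation "
            "to the ontology header"
        )
    elif len(candidates) > 1:
        status = CheckStatus.ERROR
        messages.append(
            f"{len(candidates)} dcterms:license annotations found; exactly one is expected"
        )
    elif registry_canonical is not None:
        try:
            doc_canonical = canonicalize_license_url(candidates[0])
        except ValueError:
            doc_canonical = None
            status = CheckStatus.ERROR
            messages.append(
                f"ontology license annotation {candidates[0]!r} is not a URL"
            )
        if doc_canonical is not None and doc_canonical != registry_canonical:
            status = CheckStatus.ERROR
            messages.append(
                f"ontology license {candidates[0]} does not match the registry "
                f"license {lic.url}; the two must be the same"
            )

    if wrong_property:
        status = max(status, CheckStatus.WARN)
        for prop in wrong_property:
            messages.append(
                f"license-like annotation under {prop}; "
                "use the correct dcterms:license property instead"
            )

    return CheckResult("FP1", status, messages, {"wrong_property": len(wrong_property)})


# ---------------------------------------------------------------------------
# FP2 Common Format


def check_format(load_result: OntologyDocument | FormatError) -> CheckResult:
    """FP2: the ontology must load from an accepted concrete syntax; a
    successful load is taken as evidence of a good format."""
    if isinstance(load_result, FormatError):
        return CheckResult(
            "FP2",
            CheckStatus.ERROR,
            [f"ontology could not be parsed: {load_result.message}"],
            {"load_failed": 1},
        )
    return CheckResult("FP2", CheckStatus.PASS, [], {"load_failed": 0})


# ---------------------------------------------------------------------------
# FP3 URI/Identifier Space


def check_uris(doc: OntologyDocument, canonical_prefix: str) -> CheckResult:
    """FP3: term IRIs in the ontology's own namespace must be
    base + PREFIX + '_' + numeric local id.

    Annotation properties are excluded (legacy OBO conversions use words
    and hashtags there); IRIs outside the ontology's namespace are
    skipped — reusing foreign terms is legal.  A prefix that matches only
    case-insensitively is reported as a violation.
    """
    messages: list[str] = []
    missing_underscore = nonnumeric = case_mismatch = checked = 0

    for ent in doc.entities:
        if ent.category is EntityCategory.ANNOTATION_PROPERTY:
            continue
        iri = ent.iri
        if not iri.startswith(OBO_PURL_BASE):
            continue
        rest = iri[len(OBO_PURL_BASE):]
        if rest.startswith(canonical_prefix):
            checked += 1
            tail = rest[len(canonical_prefix):]
            if not tail.startswith("_"):
                missing_underscore += 1
                messages.append(
                    f"{iri}: character after the prefix must be an underscore"
                )
            elif not tail[1:].isdigit() or not tail[1:]:
                nonnumeric += 1
                messages.append(
                    f"{iri}: local ID after the underscore must be numeric"
                )
        elif rest.lower().startswith(canonical_prefix.lower() + "_"):
            checked += 1
            case_mismatch += 1
            messages.append(
                f"{iri}: prefix capitalization does not match the canonical "
                f"prefix {canonical_prefix!r}"
            )

    n_violations = missing_underscore + nonnumeric + case_mismatch
    status = CheckStatus.ERROR if n_violations else CheckStatus.PASS
    return CheckResult(
        "FP3",
        status,
        messages,
        {
            "missing_underscore": missing_underscore,
            "nonnumeric_local_id": nonnumeric,
            "case_mismatch": case_mismatch,
            "checked": checked,
        },
    )


# ---------------------------------------------------------------------------
# FP4 Versioning


def check_versioning(doc: OntologyDocument) -> CheckResult:
    """FP4: the ontology header must carry a version IRI; a dated
    (YYYY-MM-DD) version IRI fully passes, an undated one is noted."""
    if not doc.version_iri:
        return CheckResult(
            "FP4",
            CheckStatus.ERROR,
            ["no version IRI found; add owl:versionIRI to the ontology header"],
            {"version_iri_missing": 1, "version_date_missing": 0},
        )
    if parse_version_date(doc.version_iri) is None:
        return CheckResult(
            "FP4",
            CheckStatus.INFO,
            [
                f"version IRI {doc.version_iri} is not in date (YYYY-MM-DD) "
                "format; version identified but recency cannot be assessed"
            ],
            {"version_iri_missing": 0, "version_date_missing": 1},
        )
    return CheckResult(
        "FP4", CheckStatus.PASS, [], {"version_iri_missing": 0, "version_date_missing": 0}
    )


# ---------------------------------------------------------------------------
# FP5 Scope


def check_scope(entry: RegistryEntry, peers: Sequence[RegistryEntry]) -> CheckResult:
    """FP5: the registry record must declare a domain; a domain shared with
    other active ontologies is reported (with the list of sharers)."""
    if not entry.domain:
        return CheckResult(
            "FP5",
            CheckStatus.ERROR,
            ["no 'domain' tag in the registry record; declare the ontology's scope"],
            {"domain_missing": 1, "shared_with": 0},
        )
    sharers = sorted(
        peer.id
        for peer in peers
        if peer.id != entry.id
        and peer.is_active
        and peer.domain
        and peer.domain.strip().lower() == entry.domain.strip().lower()
    )
    if sharers:
        return CheckResult(
            "FP5",
            CheckStatus.INFO,
            [
                f"domain {entry.domain!r} is shared with: {', '.join(sharers)}; "
                "review scope overlap"
            ],
            {"domain_missing": 0, "shared_with": len(sharers)},
        )
    return CheckResult("FP5", CheckStatus.PASS, [], {"domain_missing": 0, "shared_with": 0})


# ---------------------------------------------------------------------------
# FP6 Textual Definitions / FP12 Naming Conventions (shared engine)


def _in_annotation_scope(ent) -> bool:
    return ent.category in (
        EntityCategory.CLASS,
        EntityCategory.OBJECT_PROPERTY,
        EntityCategory.DATA_PROPERTY,
    )


def _tally_annotation_faults(
    doc: OntologyDocument, values_of: Callable[[object], list[str]]
) -> tuple[dict[str, int], dict[str, list[str]]]:
    """Count missing/multiple/duplicate annotation values over classes and
    object/data properties.

    Deprecated entities are exempt from the *missing* count (historical
    artifacts) but still participate in multiple/duplicate counting.
    Returns (counters, offenders-by-fault) with offender IRIs sorted.
    """
    scoped = [e for e in doc.entities if _in_annotation_scope(e)]
    missing = [e.iri for e in scoped if not e.deprecated and len(values_of(e)) == 0]
    multiple = [e.iri for e in scoped if len(values_of(e)) >= 2]

    by_value: dict[str, list[str]] = {}
    for ent in scoped:
        for value in values_of(ent):
            by_value.setdefault(value, []).append(ent.iri)
    duplicate = sorted(
        {iri for iris in by_value.values() if len(set(iris)) >= 2 for iri in iris}
    )
    counters = {
        "missing": len(missing),
        "multiple": len(multiple),
        "duplicate": len(duplicate),
    }
    offenders = {
        "missing": sorted(missing),
        "multiple": sorted(multiple),
        "duplicate": duplicate,
    }
    return counters, offenders


def _annotation_check(
    principle_id: str,
    doc: OntologyDocument,
    values_of: Callable[[object], list[str]],
    noun: str,
    severities: Mapping[str, CheckStatus],
    counter_prefix: str,
) -> CheckResult:
    counters, offenders = _tally_annotation_faults(doc, values_of)
    messages: list[str] = []
    status = CheckStatus.PASS
    for fault in ("missing", "multiple", "duplicate"):
        if counters[fault]:
            status = max(status, severities[fault])
            shown = ", ".join(offenders[fault][:5])
            more = "" if counters[fault] <= 5 else f" (and {counters[fault] - 5} more)"
            messages.append(
                f"{counters[fault]} entit{'y' if counters[fault] == 1 else 'ies'} "
                f"with {fault.replace('_', ' ')} {noun}: {shown}{more}"
            )
    metrics = {
        f"missing_{counter_prefix}": counters["missing"],
        f"multiple_{counter_prefix}s": counters["multiple"],
        f"duplicate_{counter_prefix}": counters["duplicate"],
    }
    return CheckResult(principle_id, status, messages, metrics)


def check_definitions(doc: OntologyDocument, config: Mapping | None = None) -> CheckResult:
    """FP6: every class and property should carry exactly one textual
    definition, distinct from every other entity's definition.

    Counts missing, multiple and duplicate definitions; the status is the
    worst configured severity among the nonzero counters.
    """
    cfg = default_config() | dict(config or {})
    severities = {
        "missing": cfg["def_missing"],
        "multiple": cfg["def_multiple"],
        "duplicate": cfg["def_duplicate"],
    }
    return _annotation_check(
        "FP6", doc, lambda e: e.definitions, "definition", severities, "definition"
    )


def check_naming(doc: OntologyDocument, config: Mapping | None = None) -> CheckResult:
    """FP12: every entity must have exactly one rdfs:label, unique within
    the ontology; counts missing, multiple and duplicate labels."""
    cfg = default_config() | dict(config or {})
    severities = {
        "missing": cfg["label_missing"],
        "multiple": cfg["label_multiple"],
        "duplicate": cfg["label_duplicate"],
    }
    return _annotation_check(
        "FP12", doc, lambda e: e.labels, "label", severities, "label"
    )


# ---------------------------------------------------------------------------
# FP7 Relations


def check_relations(
    doc: OntologyDocument, ro_index: ROIndex, own_prefix: str
) -> CheckResult:
    """FP7: object and data properties should be reused from the Relations
    Ontology (RO) rather than re-minted.

    Properties found in the RO index pass; a local property whose label
    exactly matches an RO label shadows an existing relation (the RO IRI
    is suggested); any other foreign non-RO property is flagged.
    """
    if ro_index is None or not ro_index.iris:
        raise ValueError("check_relations requires a non-empty RO index")

    messages: list[str] = []
    reused = local = shadowed = foreign = 0
    own_ns = OBO_PURL_BASE + own_prefix + "_"
    for ent in doc.entities:
        if ent.category not in (EntityCategory.OBJECT_PROPERTY, EntityCategory.DATA_PROPERTY):
            continue
        if ent.iri in ro_index.iris:
            reused += 1
        elif ent.iri.startswith(own_ns):
            local += 1
            for label in ent.labels:
                hit = ro_index.labels.get(label.strip().lower())
                if hit:
                    shadowed += 1
                    messages.append(
                        f"local property {ent.iri} is labeled {label!r}, which "
                        f"matches the RO property {hit}; consider reusing it"
                    )
        else:
            foreign += 1
            messages.append(
                f"property {ent.iri} is not a Relations Ontology property; "
                "reuse RO relations where possible"
            )
    status = CheckStatus.WARN if (shadowed or foreign) else CheckStatus.PASS
    return CheckResult(
        "FP7",
        status,
        messages,
        {
            "reused": reused,
            "local": local,
            "label_shadowed": shadowed,
            "foreign_non_ro": foreign,
        },
    )


# ---------------------------------------------------------------------------
# FP8 Documentation


def check_documentation(entry: RegistryEntry, ctx: CheckContext) -> CheckResult:
    """FP8: the registry record must carry a homepage and a description,
    and the homepage must resolve (HTTP status below 400).

    In offline mode resolution is not probed and the check reports INFO.
    """
    messages: list[str] = []
    missing = 0
    if not entry.homepage:
        missing += 1
        messages.append("no 'homepage' entry in the registry record")
    if not entry.description:
        missing += 1
        messages.append("no 'description' entry in the registry record")
    if missing:
        return CheckResult(
            "FP8", CheckStatus.ERROR, messages, {"missing_fields": missing, "unresolvable": 0}
        )
    if ctx.offline or ctx.http_prober is None:
        return CheckResult(
            "FP8",
            CheckStatus.INFO,
            ["homepage resolution not probed (offline mode)"],
            {"missing_fields": 0, "unresolvable": 0},
        )
    try:
        status_code = ctx.http_prober(entry.homepage)
    except Exception as exc:
        return CheckResult(
            "FP8",
            CheckStatus.ERROR,
            [f"homepage {entry.homepage} did not resolve: {exc}"],
            {"missing_fields": 0, "unresolvable": 1},
        )
    if status_code >= 400:
        return CheckResult(
            "FP8",
            CheckStatus.ERROR,
            [f"homepage {entry.homepage} returned HTTP status {status_code}"],
            {"missing_fields": 0, "unresolvable": 1},
        )
    return CheckResult("FP8", CheckStatus.PASS, [], {"missing_fields": 0, "unresolvable": 0})


# ---------------------------------------------------------------------------
# FP9 / FP11 / FP20 registry-presence checks


def check_registry_presence(entry: RegistryEntry, principle_id: str) -> CheckResult:
    """Registry-presence checks: FP9 requires documented usages, FP11 a
    well-formed contact (name + email), FP20 an issue-tracker URL."""
    if principle_id == "FP9":
        if entry.usages and all(u.user for u in entry.usages):
            return CheckResult("FP9", CheckStatus.PASS, [], {"usages": len(entry.usages)})
        return CheckResult(
            "FP9",
            CheckStatus.ERROR,
            ["no 'usages' entries in the registry record; document independent users"],
            {"usages": 0},
        )
    if principle_id == "FP11":
        contact = entry.contact or ContactInfo()
        problems: list[str] = []
        if not contact.label or "@" in contact.label:
            problems.append("contact entry needs a single person name (no '@')")
        email = contact.email or ""
        if email.count("@") != 1 or "." not in email.partition("@")[2]:
            problems.append("contact entry needs a well-formed email address")
        if problems:
            return CheckResult("FP11", CheckStatus.ERROR, problems, {"contact_faults": len(problems)})
        return CheckResult("FP11", CheckStatus.PASS, [], {"contact_faults": 0})
    if principle_id == "FP20":
        from .registry import _is_url  # syntactic URL shape, shared with registry rules

        if entry.tracker and _is_url(entry.tracker):
            return CheckResult("FP20", CheckStatus.PASS, [], {"tracker_missing": 0})
        return CheckResult(
            "FP20",
            CheckStatus.ERROR,
            ["no 'tracker' URL in the registry record; offer a channel for requests"],
            {"tracker_missing": 1},
        )
    raise ValueError(f"check_registry_presence does not handle {principle_id!r}")


# ---------------------------------------------------------------------------
# FP16 Maintenance


def check_maintenance(
    doc: OntologyDocument,
    today: datetime.date,
    warn_years: int = 2,
    error_years: int = 3,
) -> CheckResult:
    """FP16: the release date embedded in the version IRI must be recent.

    Age thresholds are calendar years: up to ``warn_years`` old passes,
    up to ``error_years`` warns, older errors.  Without a dated version
    IRI, recency cannot be assessed (WARN); a future date is flagged.
    """
    if not warn_years < error_years:
        raise ValueError("warn_years must be smaller than error_years")
    version_date = parse_version_date(doc.version_iri) if doc.version_iri else None
    if version_date is None:
        return CheckResult(
            "FP16",
            CheckStatus.WARN,
            ["no dated version IRI; recency cannot be assessed"],
            {"age_days": -1, "stale": 0},
        )
    age_days = (today - version_date).days
    if age_days < 0:
        return CheckResult(
            "FP16",
            CheckStatus.WARN,
            [
                f"version date {version_date} is in the future "
                "(clock skew or pre-release?)"
            ],
            {"age_days": age_days, "stale": 0},
        )
    warn_boundary = version_date + relativedelta(years=warn_years)
    error_boundary = version_date + relativedelta(years=error_years)
    if today <= warn_boundary:
        return CheckResult("FP16", CheckStatus.PASS, [], {"age_days": age_days, "stale": 0})
    if today <= error_boundary:
        return CheckResult(
            "FP16",
            CheckStatus.WARN,
            [
                f"last dated release {version_date} is more than {warn_years} "
                "years old; release an update"
            ],
            {"age_days": age_days, "stale": 1},
        )
    return CheckResult(
        "FP16",
        CheckStatus.ERROR,
        [
            f"last dated release {version_date} is more than {error_years} "
            "years old; the ontology appears unmaintained"
        ],
        {"age_days": age_days, "stale": 1},
    )


# ---------------------------------------------------------------------------
# Full battery


def canonical_prefix_for(entry: RegistryEntry, config: Mapping | None = None) -> str:
    """The namespace prefix used in term IRIs: the registry id uppercased,
    unless a preferred_prefix override is configured or curated."""
    cfg = config or {}
    return (
        cfg.get("preferred_prefix")
        or entry.extra.get("preferred_prefix")
        or entry.id.upper()
    )


def evaluate_ontology(
    entry: RegistryEntry,
    load_result: OntologyDocument | FormatError | None,
    ctx: CheckContext,
) -> DashboardRow:
    """Run all 13 principle checks for one ontology, in fixed order.

    Registry-only checks run even when the ontology failed to load;
    ontology-dependent checks then report ERROR with the loader message.
    """
    doc = load_result if isinstance(load_result, OntologyDocument) else None
    prefix = canonical_prefix_for(entry, ctx.config)
    cfg = default_config() | dict(ctx.config or {})
    ro_index = ctx.ro_index if ctx.ro_index is not None else load_ro_index()

    def unloadable(principle_id: str) -> CheckResult:
        detail = (
            f": {load_result.message}" if isinstance(load_result, FormatError) else ""
        )
        return CheckResult(
            principle_id,
            CheckStatus.ERROR,
            [f"ontology not loadable{detail}"],
            {"not_loadable": 1},
        )

    results: dict[str, CheckResult] = {}
    results["FP1"] = check_open(entry, doc)
    results["FP2"] = check_format(
        load_result if load_result is not None else FormatError("ontology document unavailable")
    )
    results["FP3"] = check_uris(doc, prefix) if doc else unloadable("FP3")
    results["FP4"] = check_versioning(doc) if doc else unloadable("FP4")
    results["FP5"] = check_scope(entry, ctx.peers)
    results["FP6"] = check_definitions(doc, cfg) if doc else unloadable("FP6")
    results["FP7"] = (
        check_relations(doc, ro_index, prefix) if doc else unloadable("FP7")
    )
    results["FP8"] = check_documentation(entry, ctx)
    results["FP9"] = check_registry_presence(entry, "FP9")
    results["FP11"] = check_registry_presence(entry, "FP11")
    results["FP12"] = check_naming(doc, cfg) if doc else unloadable("FP12")
    results["FP16"] = (
        check_maintenance(
            doc, ctx.today, cfg["maintenance_warn_years"], cfg["maintenance_error_years"]
        )
        if doc
        else unloadable("FP16")
    )
    results["FP20"] = check_registry_presence(entry, "FP20")

    ordered = {pid: results[pid] for pid in PRINCIPLE_IDS}
    return DashboardRow(
        ontology_id=entry.id, results=ordered, summary=summarize(ordered)
    )


def na_row(entry: RegistryEntry) -> DashboardRow:
    """An all-NA row for inactive or obsolete ontologies (listed, not checked)."""
    results = {
        pid: CheckResult(pid, CheckStatus.NA, [], {}) for pid in PRINCIPLE_IDS
    }
    return DashboardRow(entry.id, results, CheckStatus.NA)
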