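"""Registry metadata records: parsing, validation and license-URL handling.

The OBO registry stores one curated metadata record per ontology (title,
id, homepage, contact, license, products, activity status, ...) in YAML
under version control.  This module parses those records into
:class:`RegistryEntry` objects and validates them against the minimal
metadata model: every broken rule becomes a :class:`Violation` value,
never an exception.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Any
from urllib.parse import urlparse, urlunparse

import yaml

__all__ = [
    "ActivityStatus",
    "ContactInfo",
    "LicenseInfo",
    "ProductInfo",
    "RegistryEntry",
    "RegistryParseError",
    "Severity",
    "UsageRecord",
    "Violation",
    "ACCEPTED_LICENSES",
    "RULE_CATALOG",
    "canonicalize_license_url",
    "parse_registry",
    "serialize_registry",
    "validate_entry",
]


class ActivityStatus(str, Enum):
    """Development status of an ontology project."""

    ACTIVE = "active"
    INACTIVE = "inactive"
    ORPHANED = "orphaned"


class Severity(str, Enum):
    WARN = "WARN"
    ERROR = "ERROR"


@dataclass(frozen=True)
class ContactInfo:
    """Person responsible for the ontology: a name and an email address."""

    label: str | None = None
    email: str | None = None


@dataclass(frozen=True)
class LicenseInfo:
    """License name plus its URL; the two must agree."""

    label: str | None = None
    url: str | None = None


@dataclass(frozen=True)
class ProductInfo:
    """A released artefact, canonically ``<idspace>.owl``."""

    id: str


@dataclass(frozen=True)
class UsageRecord:
    """A documented external user of the ontology."""

    user: str
    description: str | None = None


@dataclass
class RegistryEntry:
    """One ontology's curated registry record (minimal metadata model)."""

    id: str
    title: str | None = None
    homepage: str | None = None
    contact: ContactInfo | None = None
    description: str | None = None
    license: LicenseInfo | None = None
    products: list[ProductInfo] = field(default_factory=list)
    activity_status: str | None = None
    is_obsolete: Any = False
    domain: str | None = None
    usages: list[UsageRecord] = field(default_factory=list)
    tracker: str | None = None
    extra: dict[str, Any] = field(default_factory=dict)

    @property
    def is_active(self) -> bool:
        return self.activity_status == ActivityStatus.ACTIVE.value and (
            self.is_obsolete is not True
        )


@dataclass(frozen=True)
class Violation:
    """One broken registry rule, located by a dotted field path."""

    field_path: str
    rule_id: str
    message: str
    severity: Severity = Severity.ERROR


class RegistryParseError(ValueError):
    """Raised when a registry document is structurally malformed."""


# Rule catalogue: stable rule ids -> human description.  Twelve top-level
# rules; the id format rule is split into three sub-rules so that each
# distinct fault carries its own id.
RULE_CATALOG: dict[str, str] = {
    "title_present": "Title must be present",
    "id_lowercase": "id must be lowercase",
    "id_no_space": "id must contain no spaces",
    "id_alphanumeric": "id must be alphanumeric",
    "homepage_url": "homepage must be in a URL format",
    "contact_label": "contact.label must not contain '@' and only have one label",
    "contact_email": "contact.email must be in email format and only have one email",
    "products_present": "at least the canonical ontology product must be listed",
    "products_id_format": "product ids must match '<idspace>.<ext>' or '<idspace>/<subpath>'",
    "description_present": "description must be present",
    "license_consistent": "license.label must correspond to the title of the license.url",
    "license_url_format": "license.url must be in a URL format",
    "activity_status_enum": "activity status must be one of 'active', 'inactive' or 'orphaned'",
    "obsolete_boolean": "obsoletion status must be either 'true' or 'false'",
}

# Accepted open licenses: canonical URL -> tolerated label spellings
# (compared case-insensitively).  Covers CC0 1.0 and CC BY 3.0/4.0.
ACCEPTED_LICENSES: dict[str, tuple[str, ...]] = {
    "https://creativecommons.org/publicdomain/zero/1.0": (
        "cc0 1.0",
        "cc-0 1.0",
        "cc0",
        "cc-0",
    ),
    "https://creativecommons.org/licenses/by/3.0": (
        "cc by 3.0",
        "cc-by 3.0",
    ),
    "https://creativecommons.org/licenses/by/4.0": (
        "cc by 4.0",
        "cc-by 4.0",
    ),
}


def canonicalize_license_url(url: str) -> str:
    """Normalize a license URL so registry/ontology comparisons are robust.

    Lowercases scheme and host, upgrades creativecommons.org links to
    https, and strips any trailing slash.  Idempotent by construction.

    Raises ``ValueError`` for input that is not syntactically a URL.
    """
    if not url or not isinstance(url, str):
        raise ValueError(f"not a URL: {url!r}")
    parts = urlparse(url.strip())
    if not parts.scheme or not parts.netloc:
        raise ValueError(f"not a URL: {url!r}")
    scheme = parts.scheme.lower()
    host = parts.netloc.lower()
    if host in ("creativecommons.org", "www.creativecommons.org"):
        scheme = "https"
        host = "creativecommons.org"
    path = parts.path.rstrip("/")
    return urlunparse((scheme, host, path, "", parts.query, ""))


def _is_url(value: Any) -> bool:
    if not isinstance(value, str):
        return False
    parts = urlparse(value)
    return parts.scheme in ("http", "https") and bool(parts.netloc)


def _is_email(value: Any) -> bool:
    # Syntactic only: one '@', non-empty local and domain parts, dotted domain.
    if not isinstance(value, str) or value.count("@") != 1:
        return False
    local, _, domain = value.partition("@")
    if not local or not domain or " " in value:
        return False
    head, dot, tld = domain.rpartition(".")
    return bool(head) and bool(dot) and bool(tld)


_MODELED_FIELDS = {
    "id",
    "title",
    "homepage",
    "contact",
    "description",
    "license",
    "products",
    "activity_status",
    "is_obsolete",
    "domain",
    "usages",
    "tracker",
}


def _entry_from_mapping(record: dict[str, Any]) -> RegistryEntry:
    if not isinstance(record, dict):
        raise RegistryParseError(f"registry record is not a mapping: {record!r}")
    if "id" not in record or record["id"] in (None, ""):
        raise RegistryParseError("registry record has no 'id' field")

    contact = None
    raw_contact = record.get("contact")
    if isinstance(raw_contact, dict):
        contact = ContactInfo(
            label=raw_contact.get("label"), email=raw_contact.get("email")
        )
    elif raw_contact is not None:
        contact = ContactInfo(label=str(raw_contact))

    license_info = None
    raw_license = record.get("license")
    if isinstance(raw_license, dict):
        license_info = LicenseInfo(
            label=raw_license.get("label"), url=raw_license.get("url")
        )
    elif raw_license is not None:
        license_info = LicenseInfo(label=str(raw_license))

    products = []
    for item in record.get("products") or []:
        if isinstance(item, dict) and "id" in item:
            products.append(ProductInfo(id=str(item["id"])))
        elif isinstance(item, str):
            products.append(ProductInfo(id=item))

    usages = []
    for item in record.get("usages") or []:
        if isinstance(item, dict):
            usages.append(
                UsageRecord(
                    user=str(item.get("user") or ""),
                    description=item.get("description"),
                )
            )
        elif isinstance(item, str):
            usages.append(UsageRecord(user=item))

    extra = {k: v for k, v in record.items() if k not in _MODELED_FIELDS}

    return RegistryEntry(
        id=str(record["id"]),
        title=record.get("title"),
        homepage=record.get("homepage"),
        contact=contact,
        description=record.get("description"),
        license=license_info,
        products=products,
        activity_status=record.get("activity_status"),
        is_obsolete=record.get("is_obsolete", False),
        domain=record.get("domain"),
        usages=usages,
        tracker=record.get("tracker"),
        extra=extra,
    )


def parse_registry(text: str) -> list[RegistryEntry]:
    """Parse registry YAML into entries.

    Accepts either a single-record document (a top-level mapping with an
    ``id``) or a combined listing under an ``ontologies`` key.  Unknown
    fields are preserved in :attr:`RegistryEntry.extra`, never rejected.
    """
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        where = f" at line {mark.line + 1}, column {mark.column + 1}" if mark else ""
        raise RegistryParseError(f"malformed registry document{where}: {exc}") from exc

    if data is None:
        return []
    if isinstance(data, dict) and "ontologies" in data:
        records = data["ontologies"] or []
    elif isinstance(data, dict):
        records = [data]
    elif isinstance(data, list):
        records = data
    else:
        raise RegistryParseError(f"unexpected registry document shape: {type(data)}")

    entries = [_entry_from_mapping(r) for r in records]
    seen: set[str] = set()
    for entry in entries:
        if entry.id in seen:
            raise RegistryParseError(f"duplicate ontology id in listing: {entry.id!r}")
        seen.add(entry.id)
    return entries


def _entry_to_mapping(entry: RegistryEntry) -> dict[str, Any]:
    record: dict[str, Any] = {"id": entry.id}
    if entry.title is not None:
        record["title"] = entry.title
    if entry.homepage is not None:
        record["homepage"] = entry.homepage
    if entry.contact is not None:
        record["contact"] = {
            k: v
            for k, v in (("label", entry.contact.label), ("email", entry.contact.email))
            if v is not None
        }
    if entry.description is not None:
        record["description"] = entry.description
    if entry.license is not None:
        record["license"] = {
            k: v
            for k, v in (("label", entry.license.label), ("url", entry.license.url))
            if v is not None
        }
    if entry.products:
        record["products"] = [{"id": p.id} for p in entry.products]
    if entry.activity_status is not None:
        record["activity_status"] = entry.activity_status
    record["is_obsolete"] = entry.is_obsolete
    if entry.domain is not None:
        record["domain"] = entry.domain
    if entry.usages:
        record["usages"] = [
            {k: v for k, v in (("user", u.user), ("description", u.description)) if v}
            for u in entry.usages
        ]
    if entry.tracker is not None:
        record["tracker"] = entry.tracker
    record.update(entry.extra)
    return record


def serialize_registry(entries: list[RegistryEntry]) -> str:
    """Write entries back to the combined-listing YAML dialect."""
    payload = {"ontologies": [_entry_to_mapping(e) for e in entries]}
    return yaml.safe_dump(payload, sort_keys=False, allow_unicode=True)


def _product_id_ok(product_id: str) -> bool:
    if "/" in product_id:
        idspace, _, subpath = product_id.partition("/")
        return bool(idspace) and bool(subpath) and " " not in product_id
    idspace, dot, ext = product_id.rpartition(".")
    return bool(idspace) and bool(dot) and ext.isalnum() and " " not in product_id


def validate_entry(entry: RegistryEntry) -> list[Violation]:
    """Apply the minimal-metadata rules; one Violation per broken rule.

    An empty list means the record conforms.  Violations are data, not
    exceptions: a record with several faults reports all of them.
    """
    violations: list[Violation] = []

    def flag(path: str, rule: str, msg: str, severity: Severity = Severity.ERROR):
        violations.append(Violation(path, rule, msg, severity))

    if not entry.title:
        flag("title", "title_present", "ontology title is missing")

    if any(c.isupper() for c in entry.id):
        flag("id", "id_lowercase", f"id {entry.id!r} contains uppercase characters")
    if any(c.isspace() for c in entry.id):
        flag("id", "id_no_space", f"id {entry.id!r} contains whitespace")
    if any(not (c.isalnum() or c.isspace()) for c in entry.id.lower()):
        flag("id", "id_alphanumeric", f"id {entry.id!r} contains non-alphanumeric characters")

    if not _is_url(entry.homepage):
        flag("homepage", "homepage_url", f"homepage {entry.homepage!r} is not a URL")

    contact = entry.contact or ContactInfo()
    if not contact.label or "@" in contact.label:
        flag(
            "contact.label",
            "contact_label",
            f"contact label {contact.label!r} must be a single name without '@'",
        )
    if not _is_email(contact.email):
        flag(
            "contact.email",
            "contact_email",
            f"contact email {contact.email!r} is not in email format",
        )

    if not entry.products:
        flag("products", "products_present", "no products listed (expected at least the canonical id.owl)")
    else:
        for i, product in enumerate(entry.products):
            if not _product_id_ok(product.id):
                flag(
                    f"products[{i}].id",
                    "products_id_format",
                    f"product id {product.id!r} does not match '<idspace>.<ext>' or '<idspace>/<subpath>'",
                )

    if not entry.description:
        flag("description", "description_present", "ontology description is missing")

    lic = entry.license or LicenseInfo()
    if not _is_url(lic.url):
        flag("license.url", "license_url_format", f"license url {lic.url!r} is not a URL")
    else:
        canonical = canonicalize_license_url(lic.url)
        accepted_labels = ACCEPTED_LICENSES.get(canonical)
        if accepted_labels is not None:
            label = (lic.label or "").strip().lower()
            if label not in accepted_labels:
                flag(
                    "license.label",
                    "license_consistent",
                    f"license label {lic.label!r} does not correspond to {lic.url}",
                )

    if entry.activity_status not in {s.value for s in ActivityStatus}:
        flag(
            "activity_status",
            "activity_status_enum",
            f"activity status {entry.activity_status!r} must be one of "
            "'active', 'inactive' or 'orphaned'",
        )

    if not isinstance(entry.is_obsolete, bool):
        flag(
            "is_obsolete",
            "obsolete_boolean",
            f"obsoletion status {entry.is_obsolete!r} must be a boolean",
        )

    return violations
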