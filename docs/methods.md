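# Methods

## What is being modeled

A federated ontology registry holds, for every member ontology, a curated
metadata record and a released OWL document.  `obodash` treats principle
compliance as a pure function of those two artefacts plus a small shared
context (the evaluation date, the set of peer records, a Relations
Ontology property index, and an optional homepage prober).  Nothing else
— no reasoning, no import-closure resolution, no cross-ontology logic —
enters the verdicts, so every result is reproducible from the inputs.

## Status model

Check outcomes are graded on a total order `PASS < INFO < WARN < ERROR`,
with `NA` outside the order for entries that were listed but not checked
(inactive or obsolete projects).  A row's summary is the maximum over its
non-NA cells; an all-NA row summarizes as NA.  Published compliance
matrices show binary pass/fail cells; the graded vocabulary preserves
strictly more information (e.g. "homepage present but unprobed" vs
"homepage missing") and degrades to pass/fail by thresholding at WARN.
The command-line pipeline maps ERROR to a nonzero exit code and treats
WARN/INFO as success, which makes the tool usable as a CI gate without
blocking on advisory findings.

## Registry validation

Records are YAML — either one record per file or a combined `ontologies`
listing.  Unknown fields are preserved, never rejected: real registries
carry many optional fields beyond the minimal model, and a validator that
chokes on them would be useless in practice.  Validation applies twelve
rules (title, id format, homepage URL, contact label, contact email,
products present, product id format, description, license label/URL
agreement, license URL format, activity-status enum, boolean obsoletion
flag).  The id rule is internally three sub-rules with distinct
identifiers — lowercase, no whitespace, alphanumeric — so that an id like
`"OBI 2"` reports its two faults separately.  Email validation is
syntactic only (one `@`, non-empty local and domain parts, dotted
domain); probing mail servers would make validation non-deterministic and
unusable offline.  An empty products list is a validation error: every
released ontology has at least its canonical `id.owl` artefact.

## License handling

The accepted open licenses are CC0 1.0, CC BY 3.0 and CC BY 4.0.
"CC BY 3.0 or later" is implemented as exactly {3.0, 4.0} until newer
versions are added to the table.  Because the same license is written
many ways in the wild (`http` vs `https`, trailing slash, host case), all
comparisons go through a canonicalizer that lowercases scheme and host,
upgrades creativecommons.org links to https and strips trailing slashes;
it is idempotent by construction.  Label↔URL agreement tolerates the
common spellings (`CC BY 4.0`, `CC-BY 4.0`), compared case-insensitively;
the tolerated-spelling table is the single source of truth for both the
registry rule and the openness check.  On the ontology side the canonical
property is `dcterms:license`; values found under the legacy Dublin Core
elements `license`/`rights` properties (or `dcterms:rights`) are reported
as wrong-property uses.

## Ontology fact extraction

Documents are parsed with rdflib from RDF/XML or Turtle (sniffed by
content when no hint is given).  The OBO flat-file format is out of
scope: dashboards consume released `.owl` products.  Entities are
recognized from explicit declaration axioms plus subjects of label or
definition annotations (defaulting to class); blank nodes are never
entities.  Textual definitions are read from the OBO convention property
`IAO:0000115`; deprecation from `owl:deprecated "true"`.  A document with
several version IRIs keeps the first (in IRI sort order, for
determinism) and records a loader warning — checks must still run over
malformed-but-parseable input.  Parse failure is itself a first-class
value (`FormatError`) that feeds the Common Format check; only an
unreadable path raises.

Version dates are extracted from the version IRI as a `YYYY-MM-DD` path
segment and must be real calendar dates: `2021-02-30` is rejected, not
coerced.

## Check-specific decisions

- **Identifier scheme (FP3).**  The canonical prefix is the registry id
  uppercased, overridable by a `preferred_prefix` key (mixed-case
  idspaces exist).  Matching is case-sensitive; a term whose prefix
  matches only case-insensitively is counted as its own violation class
  rather than silently skipped.  Annotation properties are exempt (legacy
  conversions use words and hashtags there); IRIs outside the ontology's
  namespace are skipped because term reuse is legal and encouraged.
- **Definitions/labels (FP6, FP12).**  One shared counting engine tallies
  missing, multiple and duplicate values over classes and object/data
  properties.  Deprecated entities are exempt from the *missing* counts
  (they are historical artifacts kept for identifier stability) but still
  participate in multiple/duplicate counting.  Default severities:
  missing definition WARN, everything else ERROR — mirroring common
  ontology-report conventions; all severities are overridable through the
  profile file.
- **Relations (FP7).**  Properties are classified against a shipped
  two-column (IRI, label) index of Relations Ontology properties: reused
  (in the index), local (in the ontology's own namespace — flagged only
  when its label shadows an RO label, with the RO IRI suggested), or
  foreign non-RO (flagged).  The check is WARN-only: relation reuse is a
  should, not a must, and the published check only compares.  The shipped
  index is a ~23-row curated subset sufficient for testing; a production
  deployment would regenerate it from an RO release.
- **Scope (FP5).**  Domain comparison is case-insensitive exact string
  equality over active, non-obsolete peers — a tag comparison, not
  semantic matching.  A shared domain is INFO (overlap is reviewable, not
  wrong); a missing tag is ERROR.
- **Documentation (FP8).**  Homepage probing follows at most 5 redirects
  with a 10 s timeout, HEAD with GET fallback, behind a URL → status-code
  contract so tests and offline runs substitute a stub.  Offline, the
  check reports INFO rather than guessing.
- **Maintenance (FP16).**  Recency thresholds are calendar years applied
  with `dateutil` arithmetic: a release up to `warn_years` (default 2)
  old passes, up to `error_years` (default 3) warns, older errors;
  transitions happen exactly at `version_date + N years`.  The cutoffs
  are non-normative defaults — no community standard fixes them — and are
  configurable.  Future-dated releases warn (clock skew or pre-release).

## Fixture generator

The generator emulates a minimal but complete member project: a
conformant registry record and a Turtle ontology with (by default) five
classes (one deprecated), one object property reused from RO, the
definition annotation property, a dated version IRI 60 days before the
fixed reference date 2021-05-15, and a CC BY 4.0 license declared in both
artefacts.  The fixed reference date makes maintenance outcomes
reproducible; the seed moves the local identifier block and contact
details, so distinct seeds give distinct bytes while the same spec always
regenerates identical bytes.

Each of the 24 catalogued violation kinds perturbs exactly the artefacts
its fault requires and carries an expected per-principle outcome map.
Three kinds necessarily touch more than one cell, and their expected maps
say so: a truncated file fails every ontology-dependent check, and the
two version-IRI kinds couple Versioning with Maintenance (both read the
version IRI).  Running the full battery over every seeded fixture and
comparing against the expected maps is the suite's central
self-consistency oracle.

What the generator does **not** emulate: large ontologies, OWL constructs
beyond declarations and annotations, import closures, non-ASCII content,
registry records with rich optional metadata, or real network behaviour
(homepage faults are realized through the stubbed prober).  Passing tests
therefore demonstrate the correctness of the decision logic on
well-understood inputs, not robustness against the full variety of
published ontologies.

## Numerical and procedural choices

- Problem sizes: unit fixtures use ≤ 20 entities; the counter-engine
  cross-check runs 100 seeded random documents against an independent
  quadratic per-entity tally; end-to-end runs use three-ontology corpora.
  These sizes exercise every code path while keeping the whole suite in
  the tens of seconds.
- Determinism: all extracted fact lists are sorted; JSON is rendered with
  sorted keys; timestamps exist only in caller-supplied run metadata.
  Two runs over identical inputs (offline, fixed date) are byte-identical
  across all output formats.
- Ties and degenerate inputs: an empty ontology passes the content checks
  vacuously; an entity repeating the same definition value twice on
  itself counts as *multiple*, not *duplicate* (duplication requires two
  distinct entities); worst-of over an empty status set is NA.

## Known limitations

Single-ontology evaluation only — no cross-ontology consistency checks.
Loadability is accepted as evidence of good format; no OWL profile
validation.  Relation reuse is judged against a subset index, so foreign
non-RO warnings depend on index completeness.  Collaboration practices
(FP10) are not mechanically checkable and are excluded by design.
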