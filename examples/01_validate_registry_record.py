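"""Validate a curated registry metadata record against the minimal model.

Parses a single-ontology YAML record, applies the metadata rules (title
present, lowercase id, URL-shaped homepage, one contact name + email,
license label/URL agreement, ...) and prints each broken rule.
"""

from obodash import parse_registry, validate_entry

RECORD = """\
id: Obi
title: Ontology for Biomedical Investigations
homepage: http://obi-ontology.org/
contact:
  label: bpeters@lji.org
  email: bpeters@lji.org
products:
  - id: obi.owl
description: An integrated ontology for the description of life science and clinical investigations
license:
  label: CC0 1.0
  url: https://creativecommons.org/licenses/by/4.0/
activity_status: active
is_obsolete: false
"""

entry = parse_registry(RECORD)[0]
violations = validate_entry(entry)

print(f"record {entry.id!r}: {len(violations)} violation(s)")
for v in violations:
    print(f"  [{v.severity.value}] {v.rule_id} at {v.field_path}: {v.message}")

# Three rules fire: the id is capitalized, the contact label is an email
# address, and the license label "CC0 1.0" names a different license than
# the CC BY 4.0 URL.  A conformant record prints zero violations.
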