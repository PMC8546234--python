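"""Assemble a multi-ontology dashboard and write the static report files.

Generates a three-ontology corpus (one clean, one with a missing
definition, one with a registry/ontology license mismatch), evaluates
every entry, and writes dashboard.{html,json,tsv} plus one detail page
per ontology under ./dashboard_out/.
"""

import dataclasses
from pathlib import Path

import yaml

from obodash import assemble_grid, evaluate_ontology, load_ontology, parse_registry, write_dashboard
from obodash.fixtures import FixtureSpec, generate_fixture, make_context

specs = [
    FixtureSpec(idspace="aaa", seed=1),
    FixtureSpec(idspace="bbb", seed=2, violations=("def_missing",)),
    FixtureSpec(idspace="ccc", seed=3, violations=("license_mismatch",)),
]
domains = {"aaa": "anatomy", "bbb": "behavior", "ccc": "chemistry"}

records, ontologies = [], {}
for spec in specs:
    registry_text, ontology_bytes, _ = generate_fixture(spec)
    record = yaml.safe_load(registry_text)
    record["domain"] = domains[spec.idspace]
    records.append(record)
    ontologies[spec.idspace] = ontology_bytes

entries = parse_registry(yaml.safe_dump({"ontologies": records}))
rows = []
for spec, entry in zip(specs, entries):
    ctx = dataclasses.replace(make_context(spec), peers=entries)
    rows.append(evaluate_ontology(entry, load_ontology(ontologies[spec.idspace]), ctx))

grid = assemble_grid(rows, {"today": "2021-05-15", "offline": "true"})
written = write_dashboard(grid, Path("dashboard_out"))

print("summary column:")
for row in grid.rows:
    print(f"  {row.ontology_id}: {row.summary.name}")
print(f"\nwrote {len(written)} files under dashboard_out/")

# aaa summarizes INFO (clean, homepage unprobed), bbb WARN (one class
# lacks a definition), ccc ERROR (ontology license CC0 does not match the
# registry's CC BY 4.0).  Open dashboard_out/dashboard.html for the grid;
# each ontology id links to its drill-down report.
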