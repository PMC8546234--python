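"""Seed a single known fault and watch exactly one check flip.

The fixture generator can plant any of 24 catalogued violation kinds
(e.g. a duplicated textual definition).  Each kind maps to one target
principle; the rest of the dashboard row is unchanged.
"""

from obodash import evaluate_ontology, load_ontology, parse_registry
from obodash.fixtures import FixtureSpec, generate_fixture, make_context, violation_catalog


def statuses(spec):
    registry_text, ontology_bytes, _ = generate_fixture(spec)
    entry = parse_registry(registry_text)[0]
    row = evaluate_ontology(entry, load_ontology(ontology_bytes), make_context(spec))
    return {pid: r.status.name for pid, r in row.results.items()}


clean = statuses(FixtureSpec())
seeded = statuses(FixtureSpec(violations=("def_duplicate",)))

print("cells that changed after seeding 'def_duplicate':")
for pid in clean:
    if clean[pid] != seeded[pid]:
        print(f"  {pid}: {clean[pid]} -> {seeded[pid]}")

print(f"\ncatalogue holds {len(violation_catalog())} seedable kinds:")
for kind, target, description in violation_catalog()[:5]:
    print(f"  {kind:24s} -> {target:5s} {description}")
print("  ...")

# Only FP6 (Textual Definitions) flips, from PASS to ERROR: the two
# classes now share an identical definition string.
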