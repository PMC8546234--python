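# obodash

Automated principle checks and dashboard reports for federated ontology
registries, in the style of the OBO Foundry.

Communities that maintain large collections of interoperable biomedical
ontologies govern them with shared principles — open licensing, a common
format, a disciplined identifier scheme, documented versioning,
maintenance and points of contact.  Reviewing those principles by hand
does not scale past a handful of projects.  `obodash` turns thirteen
automatable principles into executable checks over the two artefacts
every registered ontology has:

1. its **curated registry record** (YAML metadata: title, id, homepage,
   contact, description, license, products, activity status, domain,
   usages, tracker), and
2. its **released OWL document** (RDF/XML or Turtle).

Each ontology gets one graded result per principle
(`PASS < INFO < WARN < ERROR`, with `NA` for entries not checked), and
the results are assembled into a dashboard grid — one row per ontology,
one column per principle, a final worst-of **Summary** column — rendered
as static HTML with per-ontology drill-down reports, plus lossless JSON
and a compact TSV.

## The checks

| id   | Principle                     | What is checked |
|------|-------------------------------|-----------------|
| FP1  | Open                          | registry license is CC0 1.0 / CC BY 3.0 / CC BY 4.0 with agreeing label and URL; the ontology carries the same license under `dcterms:license` (legacy Dublin Core properties are flagged) |
| FP2  | Common Format                 | the document parses from an accepted concrete syntax |
| FP3  | URI/Identifier Space          | term IRIs in the ontology's namespace are `http://purl.obolibrary.org/obo/` + `PREFIX` + `_` + numeric id (annotation properties exempt, foreign terms skipped) |
| FP4  | Versioning                    | an `owl:versionIRI` is present; dated (`YYYY-MM-DD`) version IRIs fully pass |
| FP5  | Scope                         | a `domain` tag exists; domains shared with other active ontologies are listed |
| FP6  | Textual Definitions           | no missing, multiple or duplicate definitions (`IAO:0000115`) over classes and properties |
| FP7  | Relations                     | object/data properties are reused from the Relations Ontology; local relabelings of RO relations and foreign properties are flagged |
| FP8  | Documentation                 | homepage and description exist; the homepage resolves (HTTP < 400; not probed offline) |
| FP9  | Documented Plurality of Users | the record documents `usages` |
| FP11 | Locus of Authority            | the record names one contact person with a well-formed email |
| FP12 | Naming Conventions            | no missing, multiple or duplicate `rdfs:label` values |
| FP16 | Maintenance                   | the dated release is recent (defaults: WARN after 2 years, ERROR after 3) |
| FP20 | Responsiveness                | the record carries an issue-tracker URL |

FP10 (Commitment to Collaboration) cannot be judged mechanically and is
deliberately absent from every result.

## Worked example

The package ships a deterministic fixture generator that builds a
registry record and a matching Turtle ontology, clean or with exactly one
of 24 catalogued faults.  `examples/02_check_single_ontology.py` builds a
clean five-class fixture and runs the battery:

```
FP1   Open                           PASS
FP2   Common Format                  PASS
FP3   URI/Identifier Space           PASS
FP4   Versioning                     PASS
FP5   Scope                          PASS
FP6   Textual Definitions            PASS
FP7   Relations                      PASS
FP8   Documentation                  INFO
      - homepage resolution not probed (offline mode)
FP9   Documented Plurality of Users  PASS
FP11  Locus of Authority             PASS
FP12  Naming Conventions             PASS
FP16  Maintenance                    PASS
FP20  Responsiveness                 PASS

summary: INFO
```

Twelve checks pass; Documentation reports INFO because the run is
offline, and the summary is the worst cell in the row.  Seeding a single
fault flips exactly its target principle
(`examples/03_seeded_violation.py`):

```
cells that changed after seeding 'def_duplicate':
  FP6: PASS -> ERROR
```

The other examples validate a deliberately broken registry record and
build a three-ontology dashboard (`examples/04_build_dashboard.py`
prints `aaa: INFO`, `bbb: WARN`, `ccc: ERROR` and writes
`dashboard_out/dashboard.html`).

The same pipeline is available from the shell:

```sh
obodash dashboard --registry registry.yml --ontologies ontologies/ \
    --out out/ --offline --today 2021-05-15
obodash validate-registry --registry registry.yml --json
obodash check-one --registry registry.yml --ontology exf.ttl --offline
obodash fixtures generate --spec spec.yml --out fixtures/
```

With `--offline` and `--today` fixed, the whole run is a pure function of
its input files; the exit code is nonzero iff any ontology's summary is
ERROR.

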