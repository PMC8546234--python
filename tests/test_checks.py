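"""Unit tests for the individual principle checks."""

import dataclasses
import datetime
import random

import pytest

from obodash.checks import (
    CheckContext,
    CheckStatus,
    PRINCIPLE_IDS,
    ROIndex,
    check_definitions,
    check_documentation,
    check_format,
    check_maintenance,
    check_naming,
    check_open,
    check_registry_presence,
    check_relations,
    check_scope,
    check_uris,
    check_versioning,
    evaluate_ontology,
    load_ro_index,
    summarize,
)
from obodash.ontology import (
    EntityCategory,
    EntityRecord,
    FormatError,
    OntologyDocument,
)
from obodash.registry import ContactInfo, LicenseInfo, parse_registry
from .conftest import run_fixture

TODAY = datetime.date(2021, 5, 15)

CC_BY_4 = "https://creativecommons.org/licenses/by/4.0/"
CC0 = "https://creativecommons.org/publicdomain/zero/1.0/"
DCTERMS_LICENSE = "http://purl.org/dc/terms/license"


def doc_with_license(url, prop=DCTERMS_LICENSE):
    return OntologyDocument(annotations={prop: [url]})


def make_class(iri, labels=(), definitions=(), deprecated=False, category=EntityCategory.CLASS):
    return EntityRecord(
        iri=iri,
        category=category,
        labels=list(labels),
        definitions=list(definitions),
        deprecated=deprecated,
    )


class TestOpen:
    def test_matching_accepted_license_passes(self, obi_entry):
        result = check_open(obi_entry, doc_with_license(CC_BY_4))
        assert result.status is CheckStatus.PASS

    def test_registry_and_ontology_licenses_must_agree(self, obi_entry):
        result = check_open(obi_entry, doc_with_license(CC0))
        assert result.status is CheckStatus.ERROR
        assert any("does not match" in m for m in result.messages)

    def test_non_open_license_rejected(self, obi_entry):
        entry = dataclasses.replace(
            obi_entry,
            license=LicenseInfo("GPL-3.0", "https://www.gnu.org/licenses/gpl-3.0.html"),
        )
        result = check_open(entry, doc_with_license("https://www.gnu.org/licenses/gpl-3.0.html"))
        assert result.status is CheckStatus.ERROR
        assert any("not an accepted open license" in m for m in result.messages)

    def test_missing_ontology_annotation(self, obi_entry):
        result = check_open(obi_entry, OntologyDocument())
        assert result.status is CheckStatus.ERROR
        assert any("license annotation not found" in m for m in result.messages)

    def test_absent_document_is_an_error(self, obi_entry):
        assert check_open(obi_entry, None).status is CheckStatus.ERROR

    def test_wrong_property_flagged(self, obi_entry):
        doc = doc_with_license(CC_BY_4, prop="http://purl.org/dc/elements/1.1/license")
        result = check_open(obi_entry, doc)
        assert result.status is CheckStatus.ERROR  # no dcterms candidate at all
        assert any("dcterms:license" in m for m in result.messages)
        assert result.metrics["wrong_property"] == 1

    def test_http_and_trailing_slash_variants_compare_equal(self, obi_entry):
        doc = doc_with_license("http://creativecommons.org/licenses/by/4.0")
        assert check_open(obi_entry, doc).status is CheckStatus.PASS


class TestFormat:
    def test_loaded_document_passes(self, clean_doc):
        assert check_format(clean_doc).status is CheckStatus.PASS

    def test_format_error_reported(self):
        result = check_format(FormatError("unexpected end of file"))
        assert result.status is CheckStatus.ERROR
        assert "unexpected end of file" in result.messages[0]

    def test_empty_but_well_formed_ontology_passes(self):
        assert check_format(OntologyDocument()).status is CheckStatus.PASS


class TestUris:
    BASE = "http://purl.obolibrary.org/obo/"

    def _doc(self, *iris, category=EntityCategory.CLASS):
        return OntologyDocument(entities=[make_class(i, category=category) for i in iris])

    def test_conformant_iris_pass(self):
        doc = self._doc(self.BASE + "EXF_0000001", self.BASE + "EXF_0000002")
        result = check_uris(doc, "EXF")
        assert result.status is CheckStatus.PASS
        assert result.metrics["checked"] == 2

    def test_missing_underscore(self):
        result = check_uris(self._doc(self.BASE + "EXF0000003"), "EXF")
        assert result.status is CheckStatus.ERROR
        assert result.metrics["missing_underscore"] == 1

    def test_nonnumeric_local_id(self):
        result = check_uris(self._doc(self.BASE + "EXF_abc"), "EXF")
        assert result.status is CheckStatus.ERROR
        assert result.metrics["nonnumeric_local_id"] == 1

    def test_foreign_terms_are_skipped(self):
        doc = self._doc(self.BASE + "GO_0008150", "https://example.org/thing")
        result = check_uris(doc, "EXF")
        assert result.status is CheckStatus.PASS
        assert result.metrics["checked"] == 0

    def test_annotation_properties_excluded(self):
        doc = self._doc(self.BASE + "EXF_subset#word", category=EntityCategory.ANNOTATION_PROPERTY)
        assert check_uris(doc, "EXF").status is CheckStatus.PASS

    def test_case_insensitive_prefix_near_miss_is_flagged(self):
        result = check_uris(self._doc(self.BASE + "exf_0000001"), "EXF")
        assert result.status is CheckStatus.ERROR
        assert result.metrics["case_mismatch"] == 1


class TestVersioning:
    def test_dated_version_iri_passes(self):
        doc = OntologyDocument(version_iri="http://purl.obolibrary.org/obo/exf/2021-04-06/exf.owl")
        assert check_versioning(doc).status is CheckStatus.PASS

    def test_absent_version_iri_is_an_error(self):
        assert check_versioning(OntologyDocument()).status is CheckStatus.ERROR

    def test_non_date_version_iri_is_info(self):
        doc = OntologyDocument(version_iri="http://purl.obolibrary.org/obo/exf/v1.2/exf.owl")
        result = check_versioning(doc)
        assert result.status is CheckStatus.INFO
        assert any("recency cannot be assessed" in m for m in result.messages)


class TestScope:
    def _peers(self):
        return parse_registry(
            "ontologies:\n"
            "  - {id: aex, domain: anatomy, activity_status: active, is_obsolete: false}\n"
            "  - {id: hex, domain: health, activity_status: active, is_obsolete: false}\n"
        )

    def test_shared_domain_lists_the_sharers(self, obi_entry):
        entry = dataclasses.replace(obi_entry, domain="anatomy")
        result = check_scope(entry, self._peers())
        assert result.status is CheckStatus.INFO
        assert "aex" in result.messages[0]
        assert result.metrics["shared_with"] == 1

    def test_missing_domain_is_an_error(self, obi_entry):
        assert check_scope(obi_entry, self._peers()).status is CheckStatus.ERROR

    def test_unique_domain_passes(self, obi_entry):
        entry = dataclasses.replace(obi_entry, domain="phenotype")
        assert check_scope(entry, self._peers()).status is CheckStatus.PASS

    def test_inactive_peers_do_not_count(self, obi_entry):
        peers = parse_registry(
            "ontologies:\n"
            "  - {id: aex, domain: anatomy, activity_status: inactive, is_obsolete: false}\n"
        )
        entry = dataclasses.replace(obi_entry, domain="anatomy")
        assert check_scope(entry, peers).status is CheckStatus.PASS


class TestDefinitionsAndNaming:
    def test_hand_tallied_fixture(self):
        # 4 live classes: one undefined, two sharing a definition, one unique
        doc = OntologyDocument(
            entities=[
                make_class("a", labels=["a"], definitions=[]),
                make_class("b", labels=["b"], definitions=["shared def"]),
                make_class("c", labels=["c"], definitions=["shared def"]),
                make_class("d", labels=["d"], definitions=["unique def"]),
            ]
        )
        result = check_definitions(doc)
        assert result.metrics == {
            "missing_definition": 1,
            "multiple_definitions": 0,
            "duplicate_definition": 2,
        }
        assert result.status is CheckStatus.ERROR

    def test_empty_ontology_passes_vacuously(self):
        result = check_definitions(OntologyDocument())
        assert result.status is CheckStatus.PASS
        assert set(result.metrics.values()) == {0}

    def test_two_distinct_definitions_on_one_class(self):
        doc = OntologyDocument(
            entities=[make_class("a", labels=["a"], definitions=["one", "two"])]
        )
        result = check_definitions(doc)
        assert result.metrics["multiple_definitions"] == 1
        assert result.status is CheckStatus.ERROR

    def test_missing_definition_alone_is_a_warning(self):
        doc = OntologyDocument(entities=[make_class("a", labels=["a"])])
        assert check_definitions(doc).status is CheckStatus.WARN

    def test_deprecated_entities_exempt_from_missing_but_not_duplicates(self):
        doc = OntologyDocument(
            entities=[
                make_class("a", labels=["a"], definitions=["dup"], deprecated=True),
                make_class("b", labels=["b"], definitions=["dup"]),
            ]
        )
        result = check_definitions(doc)
        assert result.metrics["missing_definition"] == 0
        assert result.metrics["duplicate_definition"] == 2

    def test_label_faults_counted_by_same_engine(self):
        doc = OntologyDocument(
            entities=[
                make_class("a", labels=[], definitions=["x"]),
                make_class("b", labels=["same", "other"], definitions=["y"]),
                make_class("c", labels=["same"], definitions=["z"]),
            ]
        )
        result = check_naming(doc)
        assert result.metrics == {
            "missing_label": 1,
            "multiple_labels": 1,
            "duplicate_label": 2,
        }
        assert result.status is CheckStatus.ERROR

    def test_counters_agree_with_brute_force_oracle(self):
        # independent per-entity tally on random small documents
        for trial in range(100):
            rng = random.Random(1000 + trial)
            entities = []
            for i in range(rng.randrange(21)):
                defs = [f"def {rng.randrange(6)}" for _ in range(rng.randrange(3))]
                labels = [f"lab {rng.randrange(6)}" for _ in range(rng.randrange(3))]
                entities.append(
                    make_class(
                        f"e{i}",
                        labels=labels,
                        definitions=defs,
                        deprecated=rng.random() < 0.2,
                    )
                )
            doc = OntologyDocument(entities=entities)

            def oracle(values_of):
                missing = sum(
                    1 for e in entities if not e.deprecated and not values_of(e)
                )
                multiple = sum(1 for e in entities if len(values_of(e)) > 1)
                duplicate = 0
                for e in entities:
                    others = [o for o in entities if o is not e]
                    if any(
                        set(values_of(e)) & set(values_of(o)) for o in others
                    ):
                        duplicate += 1
                return missing, multiple, duplicate

            d = check_definitions(doc).metrics
            assert oracle(lambda e: e.definitions) == (
                d["missing_definition"],
                d["multiple_definitions"],
                d["duplicate_definition"],
            )
            l = check_naming(doc).metrics
            assert oracle(lambda e: e.labels) == (
                l["missing_label"],
                l["multiple_labels"],
                l["duplicate_label"],
            )


class TestRelations:
    RO_DEVELOPS_FROM = "http://purl.obolibrary.org/obo/RO_0002202"

    def _doc(self, *entities):
        return OntologyDocument(entities=list(entities))

    def test_reused_ro_property_passes(self):
        doc = self._doc(
            make_class(self.RO_DEVELOPS_FROM, labels=["develops from"],
                       category=EntityCategory.OBJECT_PROPERTY)
        )
        result = check_relations(doc, load_ro_index(), "EXF")
        assert result.status is CheckStatus.PASS
        assert result.metrics["reused"] == 1

    def test_local_property_shadowing_an_ro_label(self):
        doc = self._doc(
            make_class(
                "http://purl.obolibrary.org/obo/EXF_8000001",
                labels=["part of"],
                category=EntityCategory.OBJECT_PROPERTY,
            )
        )
        result = check_relations(doc, load_ro_index(), "EXF")
        assert result.status is CheckStatus.WARN
        assert result.metrics["label_shadowed"] == 1
        assert any("BFO_0000050" in m for m in result.messages)

    def test_foreign_non_ro_property_warns(self):
        doc = self._doc(
            make_class("https://example.org/rel#related",
                       labels=["related to"], category=EntityCategory.OBJECT_PROPERTY)
        )
        result = check_relations(doc, load_ro_index(), "EXF")
        assert result.status is CheckStatus.WARN
        assert result.metrics["foreign_non_ro"] == 1

    def test_no_properties_passes_vacuously(self):
        assert check_relations(OntologyDocument(), load_ro_index(), "EXF").status is CheckStatus.PASS

    def test_empty_index_is_a_configuration_error(self):
        with pytest.raises(ValueError):
            check_relations(OntologyDocument(), ROIndex(frozenset(), {}), "EXF")


class TestDocumentation:
    def _ctx(self, prober=None, offline=False):
        return CheckContext(today=TODAY, http_prober=prober, offline=offline)

    def test_resolving_homepage_passes(self, obi_entry):
        result = check_documentation(obi_entry, self._ctx(prober=lambda url: 200))
        assert result.status is CheckStatus.PASS

    def test_http_404_is_an_error(self, obi_entry):
        result = check_documentation(obi_entry, self._ctx(prober=lambda url: 404))
        assert result.status is CheckStatus.ERROR

    def test_offline_mode_is_info(self, obi_entry):
        result = check_documentation(obi_entry, self._ctx(offline=True))
        assert result.status is CheckStatus.INFO

    def test_missing_description_is_an_error_even_offline(self, obi_entry):
        entry = dataclasses.replace(obi_entry, description=None)
        assert check_documentation(entry, self._ctx(offline=True)).status is CheckStatus.ERROR

    def test_transport_failure_is_non_resolution(self, obi_entry):
        def prober(url):
            raise ConnectionError("no route to host")

        result = check_documentation(obi_entry, self._ctx(prober=prober))
        assert result.status is CheckStatus.ERROR
        assert any("no route to host" in m for m in result.messages)


class TestRegistryPresence:
    def test_empty_usages_fails_fp9(self, obi_entry):
        assert check_registry_presence(obi_entry, "FP9").status is CheckStatus.ERROR

    def test_wellformed_contact_passes_fp11(self, obi_entry):
        assert check_registry_presence(obi_entry, "FP11").status is CheckStatus.PASS

    def test_contact_without_email_fails_fp11(self, obi_entry):
        entry = dataclasses.replace(obi_entry, contact=ContactInfo("Bjoern Peters", None))
        assert check_registry_presence(entry, "FP11").status is CheckStatus.ERROR

    def test_tracker_url_passes_fp20(self, obi_entry):
        entry = dataclasses.replace(
            obi_entry, tracker="https://github.com/obi-ontology/obi/issues"
        )
        assert check_registry_presence(entry, "FP20").status is CheckStatus.PASS

    def test_missing_tracker_fails_fp20(self, obi_entry):
        assert check_registry_presence(obi_entry, "FP20").status is CheckStatus.ERROR

    def test_other_principles_rejected(self, obi_entry):
        with pytest.raises(ValueError):
            check_registry_presence(obi_entry, "FP6")


class TestMaintenance:
    def _doc(self, version_date):
        return OntologyDocument(
            version_iri=f"http://purl.obolibrary.org/obo/exf/{version_date}/exf.owl"
        )

    @pytest.mark.parametrize(
        ("version_date", "expected"),
        [
            ("2021-03-16", CheckStatus.PASS),   # 60 days old
            ("2019-05-15", CheckStatus.PASS),   # exactly 2 years: on the boundary
            ("2019-05-14", CheckStatus.WARN),   # one day past the warn boundary
            ("2018-05-15", CheckStatus.WARN),   # exactly 3 years
            ("2018-05-14", CheckStatus.ERROR),  # one day past the error boundary
            ("2017-05-15", CheckStatus.ERROR),  # 4 years old
        ],
    )
    def test_year_boundary_transitions(self, version_date, expected):
        assert check_maintenance(self._doc(version_date), TODAY).status is expected

    def test_future_date_warns(self):
        result = check_maintenance(self._doc("2021-06-15"), TODAY)
        assert result.status is CheckStatus.WARN
        assert any("future" in m for m in result.messages)

    def test_undated_version_iri_warns(self):
        doc = OntologyDocument(version_iri="http://purl.obolibrary.org/obo/exf/v1.2/exf.owl")
        assert check_maintenance(doc, TODAY).status is CheckStatus.WARN

    def test_thresholds_must_be_ordered(self):
        with pytest.raises(ValueError):
            check_maintenance(self._doc("2021-03-16"), TODAY, warn_years=3, error_years=2)


class TestEvaluate:
    def test_all_thirteen_principles_in_fixed_order(self, clean_spec):
        _, row, _ = run_fixture(clean_spec)
        assert list(row.results) == PRINCIPLE_IDS
        assert "FP10" not in row.results

    def test_summary_is_worst_of(self, clean_spec):
        _, row, _ = run_fixture(clean_spec)
        assert row.summary is CheckStatus.INFO  # FP8 unprobed homepage

    def test_registry_checks_survive_unloadable_ontology(self, obi_entry):
        ctx = CheckContext(today=TODAY, offline=True)
        row = evaluate_ontology(obi_entry, FormatError("truncated"), ctx)
        assert row.results["FP2"].status is CheckStatus.ERROR
        assert row.results["FP6"].status is CheckStatus.ERROR
        assert any("not loadable" in m for m in row.results["FP6"].messages)
        # registry-side checks still produce genuine results
        assert row.results["FP11"].status is CheckStatus.PASS

    def test_inserting_an_error_forces_summary_error(self, clean_spec):
        _, row, _ = run_fixture(clean_spec)
        row.results["FP9"].status = CheckStatus.ERROR
        assert summarize(row.results) is CheckStatus.ERROR

    def test_na_excluded_from_aggregation(self, clean_spec):
        _, row, _ = run_fixture(clean_spec)
        row.results["FP9"].status = CheckStatus.NA
        assert summarize(row.results) is CheckStatus.INFO
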