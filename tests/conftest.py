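import pytest

from obodash.checks import evaluate_ontology
from obodash.fixtures import FixtureSpec, generate_fixture, make_context
from obodash.ontology import load_ontology
from obodash.registry import parse_registry

# The worked example record from the minimal-metadata model: the Ontology
# for Biomedical Investigations, fully conformant.
OBI_RECORD = """\
id: obi
title: Ontology for Biomedical Investigations
homepage: http://obi-ontology.org/
contact:
  label: Bjoern Peters
  email: bpeters@lji.org
products:
  - id: obi.owl
description: An integrated ontology for the description of life science and clinical investigations
license:
  label: CC-BY 4.0
  url: https://creativecommons.org/licenses/by/4.0/
activity_status: active
is_obsolete: false
"""


@pytest.fixture
def obi_entry():
    return parse_registry(OBI_RECORD)[0]


@pytest.fixture
def clean_spec():
    return FixtureSpec()


@pytest.fixture
def clean_doc(clean_spec):
    _, onto, _ = generate_fixture(clean_spec)
    return load_ontology(onto)


def run_fixture(spec: FixtureSpec):
    """Generate a fixture and run the full check battery over it."""
    registry_text, ontology_bytes, expected = generate_fixture(spec)
    entry = parse_registry(registry_text)[0]
    row = evaluate_ontology(entry, load_ontology(ontology_bytes), make_context(spec))
    return entry, row, expected
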