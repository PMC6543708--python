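import pytest

from prokgo.ontology import load_obo_text
from prokgo.synth import FixtureSpec, generate_corpus, generate_ontology

CHAIN_OBO = """format-version: 1.2
ontology: test

[Term]
id: GO:0000003
name: root
namespace: biological_process

[Term]
id: GO:0000002
name: middle
namespace: biological_process
is_a: GO:0000003

[Term]
id: GO:0000001
name: leaf
namespace: biological_process
alt_id: GO:0000099
is_a: GO:0000002

[Term]
id: GO:0000010
name: mf root
namespace: molecular_function

[Term]
id: GO:0000011
name: old term
namespace: biological_process
is_obsolete: true
"""


@pytest.fixture(scope="session")
def chain_graph():
    """Chain GO:0000001 -> GO:0000002 -> GO:0000003 plus an MF root and an
    obsolete term."""
    return load_obo_text(CHAIN_OBO)


@pytest.fixture(scope="session")
def default_spec():
    return FixtureSpec(seed=7)


@pytest.fixture(scope="session")
def fixture_graph(default_spec):
    _, graph = generate_ontology(default_spec)
    return graph


@pytest.fixture(scope="session")
def fixture_corpus(default_spec, fixture_graph):
    return generate_corpus(default_spec, fixture_graph)
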