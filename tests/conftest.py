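import io

import pytest

from sbgngraph import (
    Language, build_graph, generate_suite, generate_toy_metabolism,
)


@pytest.fixture(scope="session")
def all_suite_cases():
    """(spec, document) for every synthetic case in all three languages."""
    cases = []
    for lang in Language:
        cases.extend(generate_suite(lang))
    return cases


@pytest.fixture(scope="session")
def toy_doc():
    return generate_toy_metabolism(n_reactions=3, cofactor_clones=True, seed=0)


@pytest.fixture(scope="session")
def toy_graph(toy_doc):
    return build_graph(toy_doc.map, decompose=True)


def roundtrip_bytes(doc):
    from sbgngraph import write_map
    buf = io.BytesIO()
    write_map(doc, buf)
    return buf.getvalue()
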