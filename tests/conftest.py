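import pytest

import litsim as ls


@pytest.fixture(scope="session")
def example_table() -> ls.ContingencyTable:
    """Packaged 6x6 similarity-method vs reference-standard table."""
    return ls.load_example_table()


@pytest.fixture(scope="session")
def small_bundle() -> ls.SyntheticBundle:
    """Small well-separated synthetic corpus shared across tests."""
    return ls.generate(ls.CorpusSpec(mixing=0.9, docs_per_category=20, seed=11))


@pytest.fixture(scope="session")
def small_reference(small_bundle) -> ls.ReferenceData:
    return ls.build_reference(small_bundle.exemplars, first_k=200, budget=100,
                              ngram_max=1)
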