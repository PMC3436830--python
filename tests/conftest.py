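import pytest

import trnadecode as td
from trnadecode.code_tables import TrnaIsoacceptor


@pytest.fixture(scope="session")
def code():
    return td.GeneticCode.from_ncbi_id(1)


@pytest.fixture(scope="session")
def ala_family(code):
    return td.family_boxes(code, "A")[0]


@pytest.fixture(scope="session")
def ala_trnas():
    return (TrnaIsoacceptor("A", "AGC", 11), TrnaIsoacceptor("A", "UGC", 5))


@pytest.fixture(scope="session")
def ala_true_reading(ala_family, ala_trnas):
    return td.ReadingMatrix.from_codon_sets(
        ala_family, ala_trnas, [{"GCU", "GCC"}, {"GCA", "GCG"}]
    )


@pytest.fixture(scope="session")
def ala_corpus(code):
    """A moderately sized simulated alanine corpus shared across tests."""
    config = td.alanine_example(n_genes=400, seed=11)
    corpus = td.simulate_corpus(config)
    genes, _ = td.load_cds(corpus.records, code)
    return config, genes
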