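import numpy as np
import pytest

from chromex.core_io import ChromSizes, ContactMatrix, Gene, GeneAnnotation, GoDAG


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def sizes():
    return ChromSizes({"chr1": 10_000_000, "chr2": 8_000_000})


@pytest.fixture
def three_genes(sizes):
    genes = [
        Gene("geneB", "chr1", 5_000, 9_000, "-"),
        Gene("geneA", "chr1", 1_000, 5_000, "+"),
        Gene("geneC", "chr2", 100_000, 250_000, "."),
    ]
    return GeneAnnotation(genes, sizes)


@pytest.fixture
def chain_dag():
    """A is_a B is_a C with default weight 0.8."""
    return GoDAG(["A", "B", "C"], [("A", "B", "is_a"), ("B", "C", "is_a")])


@pytest.fixture
def small_contact_matrix():
    counts = np.array([[1.0, 2.0], [2.0, 3.0]])
    return ContactMatrix("chr1", "cellA", 1_000_000, counts, 2)


def random_symmetric_counts(rng, n, scale=10.0):
    upper = rng.random((n, n)) * scale
    return np.triu(upper) + np.triu(upper, 1).T
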