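import numpy as np
import pytest

from panhap import synthetic


@pytest.fixture(scope="session")
def toy_genome():
    """Small two-chromosome annotated genome shared across effect tests."""
    return synthetic.generate_annotated_genome(n_chroms=2, n_genes=14, seed=11)


@pytest.fixture(scope="session")
def labelled_variants(toy_genome):
    genome, genes = toy_genome
    counts = {"intergenic": 120, "intronic": 90, "utr": 70, "synonymous": 70,
              "missense": 70, "nonsense": 30, "frameshift": 30, "splice": 20}
    records, labels = synthetic.generate_variants(genome, genes, counts,
                                                  seed=12)
    return records, labels


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)
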