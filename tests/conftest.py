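import numpy as np
import pytest

import rloopkat as rk
from rloopkat._reference import ReferenceGenome
from rloopkat.catalog_io import GeneModel, GenomicInterval


@pytest.fixture(scope="session")
def toy_reference():
    """Tiny handmade genome for exact-context oracles.

    chrA carries known motif occurrences; chrB is a short all-A arm.
    """
    return ReferenceGenome({
        "chrA": "ATCAGTCATTCAAGTCATGACCGGATCA",
        "chrB": "AAAAAAAAAA",
    })


@pytest.fixture(scope="session")
def small_cohort():
    """Default-condition synthetic cohort, shared read-only by tests."""
    cfg = rk.SyntheticConfig(seed=101, n_samples=4)
    ref, records, expression, truth = rk.simulate(cfg)
    return cfg, ref, records, expression, truth


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def make_gene(gene_id, chrom, strand, start, end, exons=None):
    exons = exons or ((start, end),)
    return GeneModel(gene_id, chrom, strand,
                     GenomicInterval(chrom, start, end, gene_id, strand),
                     tuple(GenomicInterval(chrom, s, e) for s, e in exons))
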