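import pytest

from rddcall.io_formats import GeneModel, GenomeSequence
from rddcall.synthetic_data import make_filter_gauntlet, simulate_study, small_config


@pytest.fixture(scope="session")
def gauntlet():
    return make_filter_gauntlet()


@pytest.fixture(scope="session")
def worked_gene():
    """The hand-derived interval-arithmetic example transcript (+ strand)."""
    return GeneModel(
        "geneW", "txW", "chr1", "+", [(0, 100), (200, 300)], [(50, 100), (200, 250)]
    )


@pytest.fixture(scope="session")
def worked_gene_minus():
    return GeneModel(
        "geneW", "txWm", "chr1", "-", [(0, 100), (200, 300)], [(50, 100), (200, 250)]
    )


@pytest.fixture(scope="session")
def small_study(tmp_path_factory):
    """A fast end-to-end simulated study shared by unit tests."""
    out = tmp_path_factory.mktemp("small_study")
    return simulate_study(small_config(seed=11), str(out))


def make_genome(seq: str, chrom: str = "chr1") -> GenomeSequence:
    return GenomeSequence({chrom: seq})
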