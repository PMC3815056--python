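import pytest

from sporemap.reference_gene import build_reference_gene


@pytest.fixture(scope="session")
def reference_gene():
    return build_reference_gene()


@pytest.fixture
def toy_gene():
    """Two-exon toy gene: ATG GGT | intron | TCC TAA."""
    from sporemap.gene_model import GeneModel
    #          123456 7890123456 789012
    #          ATGGGT GTxxxxxxAG TCCTAA
    seq = "ATGGGT" + "GTAAAAAG" + "TCCTAA"
    return GeneModel(gene_id="toy", genomic_seq=seq,
                     exons=((1, 6), (15, 20)))
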