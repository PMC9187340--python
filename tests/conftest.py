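import numpy as np
import pytest

from hyperld.genomes import HaploidAlignment, GeneAnnotation, SnpTable


def make_alignment(rows, contig_id="c1", ids=None):
    """Alignment from a list of equal-length genotype strings."""
    rows = [list(r.upper()) for r in rows]
    ids = ids or [f"g{i}" for i in range(len(rows))]
    return HaploidAlignment(contig_id=contig_id, genotype_ids=ids,
                            columns=np.array(rows, dtype="<U1"))


def make_snp_table(states, positions=None, contig="c1", mafs=None,
                   classes=None, genes=None, exons=None):
    """SnpTable directly from a (m, n) 0/1 state matrix (1 = minor)."""
    import pandas as pd

    states = np.asarray(states, dtype=np.uint8)
    m, n = states.shape
    positions = list(positions) if positions is not None else list(range(m))
    counts = states.sum(axis=1)
    df = pd.DataFrame({
        "contig": contig,
        "pos": positions,
        "major": "A",
        "minor": "T",
        "maf": mafs if mafs is not None else counts / n,
        "singleton": counts == 1,
        "site_class": classes if classes is not None else "noncoding",
        "gene_id": pd.array(genes if genes is not None else [None] * m,
                            dtype="string"),
        "exon_index": pd.array(exons if exons is not None else [None] * m,
                               dtype="Int64"),
        "codon_id": pd.array([None] * m, dtype="string"),
        "aa_major": pd.array([None] * m, dtype="string"),
        "aa_minor": pd.array([None] * m, dtype="string"),
    })
    return SnpTable([f"g{i}" for i in range(n)], df, states)


@pytest.fixture
def single_gene_ann():
    return GeneAnnotation(gene_id="gene0", contig_id="c1", strand="+",
                          exons=((0, 12),))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
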