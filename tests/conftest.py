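import pytest

from splicequant.gene_model import Exon, GeneModel, Junction
from splicequant.junction_io import SampleProfile


@pytest.fixture(scope="session")
def toy_gene():
    """Six 100-nt exons on the plus strand, 1 kb introns."""
    exons = [Exon(str(i + 1), 1000 + 1100 * i, 1099 + 1100 * i) for i in range(6)]
    return GeneModel("TOY", "chrT", "+", exons)


@pytest.fixture(scope="session")
def minus_gene():
    """Mirror image of the toy gene on the minus strand (exon 1 rightmost)."""
    exons = [Exon(str(i + 1), 1000 + 1100 * i, 1099 + 1100 * i) for i in range(6)]
    hi = exons[-1].end + 1000
    mirrored = [Exon(e.label, hi - e.end, hi - e.start) for e in exons]
    return GeneModel("TOYM", "chrT", "-", mirrored)


def make_profile(gm, junction_counts, sample_id="S1", **meta):
    """Profile from {Junction: count}; gene_total_reads is the plain sum."""
    counts = {
        Junction(j.intron_start, j.intron_end, gm.strand): c
        for j, c in junction_counts.items()
    }
    return SampleProfile(
        sample_id=sample_id,
        gene_id=gm.gene_id,
        counts_by_junction=counts,
        gene_total_reads=sum(counts.values()),
        **meta,
    )


def skip_junction(gm, donor_label, acceptor_label):
    """Junction joining canonical boundaries of two exons by label."""
    return gm._junction_between(
        gm.exon_index(donor_label), gm.exon_index(acceptor_label)
    )
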