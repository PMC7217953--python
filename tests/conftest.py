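import numpy as np
import pytest

from splicesig.gene_model import (GeneModel, Junction, SplicingEvent,
                                  enumerate_events, parse_gene_model)


def gtf_line(chrom, feature, start, end, strand, gene_id, tx_id=None):
    attrs = f'gene_id "{gene_id}";'
    if tx_id:
        attrs += f' transcript_id "{tx_id}";'
    return f"{chrom}\ttest\t{feature}\t{start}\t{end}\t.\t{strand}\t.\t{attrs}"


def gtf_from_exons(gene_id, chrom, strand, transcripts):
    """transcripts: {tx_id: [(start_1based, end_1based), ...]}"""
    lines = []
    for tx_id, exons in transcripts.items():
        for s, e in exons:
            lines.append(gtf_line(chrom, "exon", s, e, strand, gene_id, tx_id))
    return "\n".join(lines) + "\n"


@pytest.fixture
def cassette_gtf():
    # 3 exons; transcript A includes e2, transcript B skips it
    return gtf_from_exons("g1", "chr1", "+", {
        "tA": [(1, 100), (201, 300), (401, 500)],
        "tB": [(1, 100), (401, 500)],
    })


@pytest.fixture
def cassette_model(cassette_gtf):
    return parse_gene_model(cassette_gtf)


@pytest.fixture
def cassette_events(cassette_model):
    return enumerate_events(cassette_model)


@pytest.fixture
def cassette_event(cassette_events):
    (ev,) = [e for e in cassette_events if e.event_type == "cassette-exon"]
    return ev


@pytest.fixture
def ir_event(cassette_events):
    return next(e for e in cassette_events
                if e.event_type == "intron-retention" and e.target_interval == (100, 200))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def mirror_model(model: GeneModel, span: int = 10_000_000,
                 flip_strand: bool = True) -> GeneModel:
    """Reflect all coordinates (x -> span - x), optionally flipping strand.

    Reflect + flip is the reverse-complement view of the same molecule, so
    event types are invariant; reflect alone swaps alt-5ss and alt-3ss.
    """
    from splicesig.gene_model import Gene, Transcript

    genes = []
    for g in model.genes:
        strand = ("-" if g.strand == "+" else "+") if flip_strand else g.strand
        txs = [Transcript(t.transcript_id,
                          sorted((span - e, span - s) for s, e in t.exons))
               for t in g.transcripts]
        genes.append(Gene(g.gene_id, g.chrom, strand, txs))
    return GeneModel(genes)
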