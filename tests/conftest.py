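import pytest

from isoannot import simulate as sim
from isoannot.core import Annotation, ExonChain, GeneModel, TranscriptModel


@pytest.fixture(scope="session")
def genome_small():
    return sim.make_genome(n_chrom=2, length=60_000, seed=11)


@pytest.fixture(scope="session")
def annot_small(genome_small):
    annot, _ = sim.make_annotation(genome_small, 12, seed=11)
    return annot


def make_tx(tx_id, chrom, strand, exons, source="isoseq", gene_id=None,
            gene_name=None):
    return TranscriptModel(tx_id, ExonChain(chrom, strand, tuple(exons)),
                           source=source, gene_id=gene_id,
                           gene_name=gene_name)


def make_annot(*gene_specs):
    """gene_specs: (gene_id, chrom, strand, [(tx_id, exons), ...])"""
    genes = []
    for gid, chrom, strand, txs in gene_specs:
        gene = GeneModel(gid, chrom, strand)
        for tx_id, exons in txs:
            gene.transcripts.append(
                make_tx(tx_id, chrom, strand, exons, source="ensembl",
                        gene_id=gid))
        genes.append(gene)
    return Annotation(genes)


def mirror_annotation(annot, genome):
    """Reflect all coordinates through the contig ends and flip strands —
    the coordinate image of reverse-complementing the genome."""
    lengths = {c: len(s) for c, s in genome.items()}
    genes = []
    for gene in annot.genes.values():
        L = lengths[gene.chrom]
        flip = "-" if gene.strand == "+" else "+"
        txs = []
        for tx in gene.transcripts:
            exons = tuple(sorted((L - e, L - s) for s, e in tx.chain.exons))
            txs.append(TranscriptModel(
                tx.transcript_id, ExonChain(tx.chrom, flip, exons),
                source=tx.source, gene_id=tx.gene_id,
                gene_name=tx.gene_name))
        genes.append(GeneModel(gene.gene_id, gene.chrom, flip,
                               transcripts=txs, gene_name=gene.gene_name))
    return Annotation(genes)


def mirror_genome(genome):
    from isoannot.core import revcomp

    return {c: revcomp(s) for c, s in genome.items()}
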