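import itertools

import numpy as np
import pysam
import pytest

from isoannot import simulate as sim
from isoannot.collapse import (
    AlignedRead,
    collapse_isoforms,
    compute_alignment_metrics,
    filter_alignments,
)
from isoannot.core import ExonChain, ValidationError


def seg(cigar, nm=None, md=None):
    rec = pysam.AlignedSegment()
    rec.query_name = "q"
    rec.cigarstring = cigar
    if nm is not None:
        rec.set_tag("NM", nm)
    if md is not None:
        rec.set_tag("MD", md)
    return rec


@pytest.mark.parametrize("cigar,nm,c,i", [
    ("100M", 0, 1.0, 1.0),
    ("10S90M", 0, 0.90, 1.0),
    ("100M", 5, 1.0, 0.95),
    ("50M1000N50M", 2, 1.0, 0.98),  # introns excluded from the edit distance
    ("5H95M", 1, 0.95, 1 - 1 / 95),
])
def test_alignment_metrics(cigar, nm, c, i):
    cov, ident = compute_alignment_metrics(seg(cigar, nm=nm))
    assert cov == pytest.approx(c)
    assert ident == pytest.approx(i)


def test_metrics_md_fallback_and_error():
    # MD with 2 mismatches plus a 1-base insertion -> edit distance 3
    cov, ident = compute_alignment_metrics(seg("50M1I49M", md="10A20C68"))
    assert cov == 1.0
    assert ident == pytest.approx((100 - 3) / 100)
    with pytest.raises(ValidationError, match="neither NM nor MD"):
        compute_alignment_metrics(seg("100M"))


def mkread(rid, exons, chrom="chr1", strand="+", c=1.0, i=1.0):
    return AlignedRead(rid, ExonChain(chrom, strand, tuple(exons)), c, i)


def test_filter_boundary_inclusive():
    reads = [mkread("a", [(0, 100)], c=0.99, i=0.95),
             mkread("b", [(0, 100)], c=0.98, i=1.0),
             mkread("c", [(0, 100)], c=1.0, i=0.949)]
    passing, rejected = filter_alignments(reads)
    assert [r.read_id for r in passing] == ["a"]
    assert rejected == 2


def test_filter_matches_brute_force_on_planted_distribution():
    rng = np.random.default_rng(31)
    reads = [mkread(f"r{k}", [(0, 100)], c=float(rng.uniform(0.97, 1.0)),
                    i=float(rng.uniform(0.93, 1.0))) for k in range(200)]
    passing, rejected = filter_alignments(reads)
    expected = [r for r in reads if r.coverage >= 0.99 and r.identity >= 0.95]
    assert passing == expected
    assert rejected == 200 - len(expected)


def test_same_intron_chain_merges_with_widest_span():
    a = mkread("a", [(100, 200), (300, 400), (500, 600)])
    b = mkread("b", [(120, 200), (300, 400), (500, 650)])
    (model,) = collapse_isoforms([a, b])
    assert model.chain.exons == ((100, 200), (300, 400), (500, 650))
    assert model.support == ("a", "b")


def test_shifted_junction_splits_models():
    a = mkread("a", [(100, 200), (300, 400)])
    b = mkread("b", [(100, 205), (305, 400)])  # junction moved 5 nt
    models = collapse_isoforms([a, b], junction_tol=0)
    assert len(models) == 2
    models = collapse_isoforms([a, b], junction_tol=5)
    assert len(models) == 1


def test_mono_exon_reciprocal_overlap_clustering():
    a = mkread("a", [(0, 1000)])
    b = mkread("b", [(400, 1400)])   # 60% reciprocal overlap with a
    c = mkread("c", [(5000, 6000)])
    models = collapse_isoforms([a, b, c], mono_exon_min_overlap=0.5)
    assert len(models) == 2
    spans = sorted(m.chain.span for m in models)
    assert spans == [(0, 1400), (5000, 6000)]


def brute_force_partition(reads, tol=0, min_ov=0.5):
    """All-pairs single-linkage grouping by the stated keys."""
    n = len(reads)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            i = parent[i]
        return i

    for i, j in itertools.combinations(range(n), 2):
        a, b = reads[i].chain, reads[j].chain
        if a.chrom != b.chrom or a.strand != b.strand:
            continue
        if a.is_mono_exon != b.is_mono_exon:
            continue
        if a.is_mono_exon:
            ov = min(a.end, b.end) - max(a.start, b.start)
            if ov > 0 and min(ov / (a.end - a.start),
                              ov / (b.end - b.start)) >= min_ov:
                parent[find(i)] = find(j)
        else:
            if len(a.introns) == len(b.introns) and all(
                    abs(x[0] - y[0]) <= tol and abs(x[1] - y[1]) <= tol
                    for x, y in zip(a.introns, b.introns)):
                parent[find(i)] = find(j)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), set()).add(reads[i].read_id)
    return {frozenset(g) for g in groups.values()}


def test_partition_matches_brute_force_oracle():
    rng = np.random.default_rng(32)
    reads = []
    for k in range(50):
        strand = "+" if rng.random() < 0.5 else "-"
        start = int(rng.integers(0, 5000))
        n_exons = int(rng.integers(1, 4))
        exons = []
        pos = start
        for _ in range(n_exons):
            length = int(rng.integers(50, 200))
            exons.append((pos, pos + length))
            pos += length + int(rng.integers(50, 150))
        reads.append(mkread(f"r{k}", exons, strand=strand))
    models = collapse_isoforms(reads)
    got = {frozenset(m.support) for m in models}
    assert got == brute_force_partition(reads)


def test_support_conservation_idempotence_permutation(genome_small,
                                                      annot_small):
    reads, truths = sim.simulate_scisoseq_reads(
        annot_small, genome_small, n_cells=5, reads_per_cell=30, seed=33,
        category_mix={"FULL_LENGTH": 1.0, "MISSING_5P": 0, "MISSING_3P": 0,
                      "NO_POLYA": 0})
    aligned = [mkread(t.read_id, chain.exons, chain.chrom, chain.strand)
               for t, chain in (
                   (t, next(tx.chain for tx in annot_small.transcripts()
                            if tx.transcript_id == t.transcript_id))
                   for t in truths)]
    models = collapse_isoforms(aligned)
    assert sum(len(m.support) for m in models) == len(aligned)
    # idempotence: collapse the models as pseudo-reads
    pseudo = [mkread(m.transcript_id, m.chain.exons, m.chain.chrom,
                     m.chain.strand) for m in models]
    again = collapse_isoforms(pseudo)
    assert {m.chain for m in again} == {m.chain for m in models}
    # permutation invariance, including transcript ids
    rng = np.random.default_rng(34)
    shuffled = list(aligned)
    rng.shuffle(shuffled)
    models2 = collapse_isoforms(shuffled)
    assert [(m.transcript_id, m.chain) for m in models2] == \
        [(m.transcript_id, m.chain) for m in models]


def test_truth_recovery_from_known_transcripts(genome_small):
    annot, _ = sim.make_annotation(genome_small, 10, seed=35)
    reads, truths = sim.simulate_scisoseq_reads(
        annot, genome_small, n_cells=5, reads_per_cell=20, seed=35,
        category_mix={"FULL_LENGTH": 1.0, "MISSING_5P": 0, "MISSING_3P": 0,
                      "NO_POLYA": 0})
    chains = {tx.transcript_id: tx.chain for tx in annot.transcripts()}
    aligned = [mkread(t.read_id, chains[t.transcript_id].exons,
                      chains[t.transcript_id].chrom,
                      chains[t.transcript_id].strand) for t in truths]
    models = collapse_isoforms(aligned)
    covered = {t.transcript_id for t in truths}
    assert {m.chain for m in models} == \
        {c for tid, c in chains.items() if tid in covered}
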