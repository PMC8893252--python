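import itertools

import numpy as np
import pytest

from isoannot.classify import (
    ALT_3,
    ALT_3_AND_5,
    ALT_5,
    FSM,
    FUSION,
    GENIC,
    INTERGENIC,
    ISM,
    NIC,
    NNC,
    INTRON_RETENTION,
    NOVEL_SITE,
    REFERENCE_MATCH,
    FilterFlags,
    classification_summary,
    classify_isoform,
    compute_filter_flags,
    detect_intron_retention,
    filter_isoforms,
    intra_priming_flag,
    rt_switching_flag,
    subclassify_fsm,
)
from isoannot.core import ExonChain, GeneModel, TranscriptModel

from conftest import make_annot, make_tx, mirror_annotation, mirror_genome

REF = make_annot(
    ("gA", "chr1", "+", [("gA.t1", [(1000, 1200), (1500, 1700),
                                    (2000, 2200), (2500, 2700)])]),
    ("gB", "chr1", "+", [("gB.t1", [(5000, 5300), (5600, 5900)])]),
    ("gC", "chr1", "-", [("gC.t1", [(8000, 8200), (8500, 8700)])]),
    ("gM", "chr1", "+", [("gM.t1", [(11000, 11800)])]),  # mono-exon gene
)


def call(exons, strand="+", ref=REF, **kw):
    tx = make_tx("q", "chr1", strand, exons)
    return classify_isoform(tx, ref, **kw)


def test_verbatim_reference_copy_is_fsm_reference_match():
    c = call([(1000, 1200), (1500, 1700), (2000, 2200), (2500, 2700)])
    assert c.category == FSM
    assert c.fsm_subcategory == REFERENCE_MATCH
    assert (c.diff_to_tss, c.diff_to_tts) == (0, 0)
    assert c.matched_ref_transcript == "gA.t1"


def test_fsm_allows_end_differences():
    c = call([(900, 1200), (1500, 1700), (2000, 2200), (2500, 3100)])
    assert c.category == FSM
    assert c.fsm_subcategory == ALT_3_AND_5
    assert (c.diff_to_tss, c.diff_to_tts) == (-100, 400)


def test_ism_consecutive_subchains():
    """Every consecutive sub-chain of the 4-exon reference is ISM; a
    non-consecutive junction subset is not."""
    ref_exons = [(1000, 1200), (1500, 1700), (2000, 2200), (2500, 2700)]
    for i, j in itertools.combinations(range(4), 2):
        if j - i == 3:
            continue  # full chain -> FSM
        sub = ref_exons[i:j + 1]
        c = call(sub)
        assert c.category == ISM, (i, j)
    # junctions 1 and 3 without junction 2: not a consecutive sub-chain
    c = call([(1000, 1200), (1500, 2200), (2500, 2700)])
    assert c.category != ISM


def test_fusion_spans_two_separate_genes():
    c = call([(1100, 1200), (1500, 1700), (2000, 2200), (2500, 2700),
              (5000, 5300), (5600, 5800)])
    assert c.category == FUSION
    assert set(c.assigned_gene_ids) == {"gA", "gB"}


def test_nic_known_sites_new_chain():
    # skips the middle exons: junction (1200, 2500) uses a known donor and
    # a known acceptor in a combination absent from the reference
    c = call([(1000, 1200), (2500, 2700)])
    assert c.category == NIC


def test_nnc_novel_site_and_intron_retention():
    c = call([(1000, 1200), (1600, 1700), (2000, 2200), (2500, 2700)])
    assert c.category == NNC and c.nnc_subcategory == NOVEL_SITE
    # one exon spanning exon2+intron+exon3 retains a reference intron but
    # introduces no junctions of its own beyond known ones
    c = call([(1000, 1200), (1500, 2200), (2500, 2700)])
    assert c.category == NNC
    assert c.nnc_subcategory == INTRON_RETENTION


def test_intergenic_and_genic():
    assert call([(20000, 20500)]).category == INTERGENIC
    c = call([(1050, 1150)])  # mono-exon inside gA
    assert c.category == GENIC
    # antisense overlap is genic, not intergenic
    c = call([(8000, 8200), (8500, 8700)], strand="+")
    assert c.category == GENIC


def test_mono_exon_fsm_requires_reciprocal_overlap():
    c = call([(11050, 11750)])
    assert c.category == FSM and c.matched_ref_transcript == "gM.t1"
    c = call([(11700, 11800)])  # tiny sliver of the mono-exon gene
    assert c.category == GENIC


def test_fsm_subcategory_rules_and_minus_strand_alt3():
    assert subclassify_fsm(0, 0) == REFERENCE_MATCH
    assert subclassify_fsm(120, 500, end_tol=50) == ALT_3_AND_5
    assert subclassify_fsm(10, 500, end_tol=50) == ALT_3
    assert subclassify_fsm(-200, 10, end_tol=50) == ALT_5
    # minus-strand: a 3' extension is a *lower* genomic start coordinate
    c = call([(7700, 8200), (8500, 8700)], strand="-")
    assert c.category == FSM and c.fsm_subcategory == ALT_3
    assert c.diff_to_tts == 300
    # symmetric plus-strand case
    c = call([(5000, 5300), (5600, 6200)])
    assert c.fsm_subcategory == ALT_3 and c.diff_to_tts == 300


def test_intron_retention_matches_brute_force_oracle():
    rng = np.random.default_rng(41)
    gene = REF.genes["gA"]
    ref_introns = [iv for t in gene.transcripts for iv in t.chain.introns]
    for _ in range(100):
        n_exons = int(rng.integers(1, 4))
        exons, pos = [], int(rng.integers(900, 1600))
        for _ in range(n_exons):
            length = int(rng.integers(100, 900))
            exons.append((pos, pos + length))
            pos += length + int(rng.integers(50, 400))
        tx = make_tx("q", "chr1", "+", exons)
        expected = any(s < istart and e > iend
                       for istart, iend in ref_introns for s, e in exons)
        assert detect_intron_retention(tx, gene) == expected


def test_every_transcript_gets_exactly_one_category(genome_small,
                                                    annot_small):
    rng = np.random.default_rng(42)
    for _ in range(50):
        chrom = f"chr{int(rng.integers(1, 3))}"
        pos = int(rng.integers(0, 50_000))
        exons, p = [], pos
        for _ in range(int(rng.integers(1, 4))):
            length = int(rng.integers(80, 600))
            exons.append((p, p + length))
            p += length + int(rng.integers(60, 500))
        c = call(exons, strand="+" if rng.random() < 0.5 else "-",
                 ref=annot_small)
        assert c.category in (FSM, ISM, NIC, NNC, FUSION, INTERGENIC, GENIC)


def test_reference_self_classification(annot_small):
    for tx in annot_small.transcripts():
        c = classify_isoform(tx, annot_small)
        assert c.category == FSM
        assert c.fsm_subcategory == REFERENCE_MATCH
        assert (c.diff_to_tss, c.diff_to_tts) == (0, 0)


def test_strand_mirror_invariance(genome_small, annot_small):
    """Reverse-complementing the genome (coordinates reflected, strands
    flipped) leaves every category and subcategory unchanged."""
    mirrored_ref = mirror_annotation(annot_small, genome_small)
    rng = np.random.default_rng(43)
    for _ in range(40):
        chrom = "chr1"
        pos = int(rng.integers(0, 55_000))
        exons, p = [], pos
        for _ in range(int(rng.integers(1, 4))):
            length = int(rng.integers(80, 600))
            exons.append((p, p + length))
            p += length + int(rng.integers(60, 400))
        strand = "+" if rng.random() < 0.5 else "-"
        tx = make_tx("q", chrom, strand, exons)
        c = classify_isoform(tx, annot_small)
        L = len(genome_small[chrom])
        m_exons = tuple(sorted((L - e, L - s) for s, e in exons))
        m_tx = make_tx("q", chrom, "-" if strand == "+" else "+", m_exons)
        m = classify_isoform(m_tx, mirrored_ref)
        assert (c.category, c.fsm_subcategory, c.nnc_subcategory) == \
            (m.category, m.fsm_subcategory, m.nnc_subcategory)
        assert (c.diff_to_tss, c.diff_to_tts) == (m.diff_to_tss,
                                                  m.diff_to_tts)


def test_intra_priming_flag_strand_aware():
    genome = {"chr1": "C" * 1000 + "A" * 20 + "C" * 1000}
    tx = make_tx("t", "chr1", "+", [(500, 1000)])  # ends right before A*20
    assert intra_priming_flag(tx, genome)
    tx = make_tx("t", "chr1", "+", [(100, 600)])
    assert not intra_priming_flag(tx, genome)
    # 5 A's of 20 is below the 0.6 fraction
    genome2 = {"chr1": "C" * 500 + "AACCC" * 4 + "C" * 500}
    tx = make_tx("t", "chr1", "+", [(100, 500)])
    assert not intra_priming_flag(tx, genome2)
    # minus strand: downstream T-run is an A-run on the transcript strand
    genome3 = {"chr1": "C" * 480 + "T" * 20 + "C" * 1000}
    tx = make_tx("t", "chr1", "-", [(500, 900)])
    assert intra_priming_flag(tx, genome3)


def test_rt_switching_planted_repeat_and_oracle():
    rng = np.random.default_rng(44)
    repeat = "ACGTACGT"
    seq = ("C" * 92 + repeat            # exonic flank ends at donor 100
           + "G" * 292 + repeat         # intronic flank ends at acceptor 400
           + "C" * 200)
    genome = {"chr1": seq}
    assert rt_switching_flag(("chr1", 100, 400, "+"), genome)
    with pytest.raises(ValueError):
        rt_switching_flag(("chr1", 100, 400, "+"), genome, repeat_len=0)
    for _ in range(50):
        g = {"chr1": "".join(rng.choice(list("ACGT"), size=1000))}
        istart, iend = 300, 700
        expected = g["chr1"][292:300] == g["chr1"][692:700]
        assert rt_switching_flag(("chr1", istart, iend, "+"), g) == expected


def test_filter_isoforms_fsm_exemption():
    txs = [make_tx(f"t{k}", "chr1", "+", [(k * 1000, k * 1000 + 500)])
           for k in range(1, 11)]
    calls = {t.transcript_id: type("C", (), {"category": FSM})()
             if t.transcript_id == "t1" else
             type("C", (), {"category": NNC})() for t in txs}
    flags = {t.transcript_id: FilterFlags(t.transcript_id) for t in txs}
    for tid in ("t1", "t2", "t3"):
        flags[tid].intra_priming = True
    flags["t4"].rt_switching = True
    report = filter_isoforms(txs, calls, flags)
    kept = {t.transcript_id for t in report.retained}
    assert kept == {"t1", "t5", "t6", "t7", "t8", "t9", "t10"}
    assert report.fsm_exempted == 1
    report = filter_isoforms(txs, calls, flags,
                             exempt_fsm_from_intra_priming=False)
    assert "t1" not in {t.transcript_id for t in report.retained}
    # no flags -> identity
    clean = {t.transcript_id: FilterFlags(t.transcript_id) for t in txs}
    assert filter_isoforms(txs, calls, clean).retained == list(txs)


def test_classification_summary_proportions(annot_small):
    calls = [classify_isoform(tx, annot_small)
             for tx in annot_small.transcripts()]
    table = classification_summary(calls)
    cats = table[table.level == "category"]
    assert cats.proportion.sum() == pytest.approx(1.0)
    assert cats.loc[cats.name == FSM, "proportion"].iloc[0] == 1.0
    subs = table[table.level == "fsm_subcategory"]
    assert subs.proportion.sum() == pytest.approx(1.0)
    with pytest.raises(ValueError):
        classification_summary([])
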