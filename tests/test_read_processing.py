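import numpy as np
import pytest

from isoannot import simulate as sim
from isoannot.core import revcomp
from isoannot.read_processing import (
    FULL_LENGTH,
    MISSING_5P,
    MISSING_BOTH,
    NO_POLYA,
    CcsRead,
    ProcessedRead,
    ReadLayout,
    clip_sample_barcode,
    deduplicate_reads,
    locate_primer,
    orient_and_classify,
    process_reads,
    trim_polya,
)

LAYOUT = ReadLayout()


def semiglobal_min_edits(pattern: str, text: str) -> int:
    """Brute-force semi-global edit distance (pattern fully aligned,
    text substring free): DP oracle independent of edlib."""
    m, n = len(pattern), len(text)
    prev = [0] * (n + 1)
    for i in range(1, m + 1):
        cur = [i] + [0] * n
        for j in range(1, n + 1):
            cost = 0 if pattern[i - 1] == text[j - 1] else 1
            cur[j] = min(prev[j - 1] + cost, prev[j] + 1, cur[j - 1] + 1)
        prev = cur
    return min(prev)


def random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def test_locate_primer_exact_identity():
    primer = LAYOUT.p5_primer
    hit = locate_primer(primer, primer, 2)
    assert (hit.start, hit.end, hit.edits) == (0, len(primer), 0)


def test_locate_primer_one_substitution_matches_oracle():
    rng = np.random.default_rng(7)
    primer = LAYOUT.p3_primer
    for _ in range(20):
        seq = random_dna(rng, 80) + primer + random_dna(rng, 80)
        pos = 80 + int(rng.integers(len(primer)))
        mutated = seq[:pos] + ("A" if seq[pos] != "A" else "C") + seq[pos + 1:]
        hit = locate_primer(mutated, primer, 2)
        assert hit is not None
        assert hit.edits == semiglobal_min_edits(primer, mutated) <= 1


def test_locate_primer_absent_matches_oracle():
    rng = np.random.default_rng(8)
    primer = LAYOUT.p5_primer
    hits = 0
    for _ in range(50):
        seq = random_dna(rng, 200)
        oracle = semiglobal_min_edits(primer, seq)
        hit = locate_primer(seq, primer, 2)
        assert (hit is None) == (oracle > 2)
        if hit is not None:
            hits += 1
            assert hit.edits == oracle
    assert hits == 0  # a 30-mer never lands within 2 edits of random 200-mers


def test_clip_sample_barcode_both_ends_and_orientations():
    rng = np.random.default_rng(9)
    body = random_dna(rng, 150)
    bc = LAYOUT.sample_barcode
    clipped = clip_sample_barcode(CcsRead("r", bc + body), LAYOUT)
    assert clipped.sequence == body
    clipped = clip_sample_barcode(CcsRead("r", body + revcomp(bc)), LAYOUT)
    assert clipped.sequence == body
    clipped = clip_sample_barcode(CcsRead("r", body), LAYOUT)
    assert clipped.sequence == body  # no barcode -> unchanged


def construct_full_length(cdna, cb, umi, tail=30, layout=LAYOUT):
    return (layout.p5_primer + cdna + "A" * tail + revcomp(umi) + revcomp(cb)
            + revcomp(layout.p3_primer))


def test_orient_and_classify_sense_antisense_symmetry():
    rng = np.random.default_rng(10)
    cdna = random_dna(rng, 300)
    cb, umi = "A" * 8 + "C" * 8, "G" * 6 + "T" * 6
    sense = construct_full_length(cdna, cb, umi)
    res_s = orient_and_classify(CcsRead("s", sense), LAYOUT)
    res_a = orient_and_classify(CcsRead("a", revcomp(sense)), LAYOUT)
    assert res_s.category == res_a.category == FULL_LENGTH
    assert res_s.raw_orientation == "sense"
    assert res_a.raw_orientation == "antisense"
    assert res_a.sequence == res_s.sequence  # reoriented to the same strand


def test_orient_and_classify_missing_5p():
    rng = np.random.default_rng(11)
    cdna = random_dna(rng, 300)
    read = (cdna + "A" * 30 + revcomp("G" * 12) + revcomp("T" * 16)
            + revcomp(LAYOUT.p3_primer))
    res = orient_and_classify(CcsRead("m5", read), LAYOUT)
    assert res.category == MISSING_5P


def test_orient_and_classify_no_structure_is_missing_both():
    rng = np.random.default_rng(12)
    res = orient_and_classify(CcsRead("x", random_dna(rng, 400)), LAYOUT)
    assert res.category == MISSING_BOTH


@pytest.mark.parametrize("seq,expected_trim,expected_tail", [
    ("ACGT" + "A" * 30, "ACGT", 30),
    ("ACGT" + "AAAAAG" + "A" * 24, "ACGT", 30),  # 1 non-A inside the tail
    ("ACGTACGT", "ACGTACGT", 0),
    ("ACGT" + "A" * 9, "ACGT" + "A" * 9, 0),     # below min length
])
def test_trim_polya_examples(seq, expected_trim, expected_tail):
    trimmed, tail = trim_polya(seq, min_polya_len=10, max_non_a=2)
    assert (trimmed, tail) == (expected_trim, expected_tail)


def test_trim_polya_matches_windowed_scan_oracle():
    rng = np.random.default_rng(13)
    for _ in range(200):
        seq = random_dna(rng, 40) + "A" * int(rng.integers(0, 40))
        trimmed, tail = trim_polya(seq, 10, 2)
        # oracle: longest suffix starting with A containing <= 2 non-A
        best = 0
        for i in range(len(seq)):
            suffix = seq[i:]
            if suffix.startswith("A") and \
                    sum(c != "A" for c in suffix) <= 2:
                best = len(suffix)
                break
        expected_tail = best if best >= 10 else 0
        assert tail == expected_tail
        assert trimmed == (seq[:len(seq) - tail] if tail else seq)


def test_extract_planted_barcodes_exact():
    rng = np.random.default_rng(14)
    cb, umi = "A" * 8 + "C" * 8, "G" * 6 + "T" * 6
    # >2 non-A bases at the 3' end keep the cdna/polyA boundary unambiguous
    cdna = "CGTG" + random_dna(rng, 293) + "GGG"
    read = CcsRead("r1", construct_full_length(cdna, cb, umi))
    result = process_reads([read], LAYOUT)
    (pr,) = result.full_length
    assert (pr.cell_barcode, pr.umi, pr.cdna) == (cb, umi, cdna)
    assert pr.polya_len == 30


def test_short_insert_rejected():
    cb, umi = "T" * 16, "C" * 12
    read = CcsRead("short", construct_full_length("ACGTA", cb, umi, tail=4))
    result = process_reads([read], LAYOUT)
    assert not result.full_length
    assert sum(result.counts.values()) == 1


def test_deduplicate_by_cb_umi_key():
    def pr(rid, cb, umi, cdna):
        return ProcessedRead(read_id=rid, category=FULL_LENGTH,
                             cell_barcode=cb, umi=umi, cdna=cdna)

    reads = [pr("r1", "AA", "CC", "ACGTACGT"),
             pr("r2", "AA", "CC", "ACGTACGTACGT"),
             pr("r3", "AA", "CC", "ACGT"),
             pr("r4", "GG", "CC", "ACGT")]  # different cb -> kept
    unique, n_dup = deduplicate_reads(reads)
    assert n_dup == 2
    assert {r.read_id for r in unique} == {"r2", "r4"}  # longest cdna wins
    # tie on length -> lexicographically smallest read id
    unique, _ = deduplicate_reads([pr("rB", "AA", "CC", "ACGT"),
                                   pr("rA", "AA", "CC", "TGCA")])
    assert unique[0].read_id == "rA"


def test_process_reads_empty_input():
    result = process_reads([], LAYOUT)
    assert result.full_length == [] and result.rejects == []
    assert sum(result.counts.values()) == 0


def test_process_reads_conservation_and_truth(genome_small, annot_small):
    reads, truths = sim.simulate_scisoseq_reads(
        annot_small, genome_small, n_cells=6, reads_per_cell=20, seed=21)
    result = process_reads(reads, LAYOUT, deduplicate=False)
    assert sum(result.counts.values()) == len(reads)
    planted = {}
    for t in truths:
        planted[t.category] = planted.get(t.category, 0) + 1
    assert dict(result.counts) == planted
    truth_by_id = {t.read_id: t for t in truths}
    for pr in result.full_length:
        t = truth_by_id[pr.read_id]
        assert pr.cell_barcode == t.cb_observed
        assert pr.umi == t.umi_observed
        assert pr.cdna == t.cdna_recoverable
        assert pr.raw_orientation == t.orientation


def test_strand_symmetry_of_processing(genome_small, annot_small):
    """Reverse-complementing a read flips raw_orientation but leaves the
    extracted cb/umi/cdna unchanged."""
    reads, _ = sim.simulate_scisoseq_reads(
        annot_small, genome_small, n_cells=3, reads_per_cell=10, seed=22,
        category_mix={FULL_LENGTH: 1.0, MISSING_5P: 0.0,
                      "MISSING_3P": 0.0, NO_POLYA: 0.0})
    flipped = [CcsRead(r.read_id, revcomp(r.sequence)) for r in reads]
    fwd = process_reads(reads, LAYOUT, deduplicate=False)
    rev = process_reads(flipped, LAYOUT, deduplicate=False)
    fwd_by_id = {r.read_id: r for r in fwd.full_length}
    rev_by_id = {r.read_id: r for r in rev.full_length}
    assert set(fwd_by_id) == set(rev_by_id)
    for rid, f in fwd_by_id.items():
        r = rev_by_id[rid]
        assert (f.cell_barcode, f.umi, f.cdna) == (r.cell_barcode, r.umi,
                                                   r.cdna)
        assert f.raw_orientation != r.raw_orientation


def test_no_full_primer_in_full_length_output(genome_small, annot_small):
    reads, _ = sim.simulate_scisoseq_reads(
        annot_small, genome_small, n_cells=4, reads_per_cell=10, seed=23)
    result = process_reads(reads, LAYOUT)
    for pr in result.full_length:
        assert LAYOUT.p5_primer not in pr.cdna
        assert LAYOUT.p3_primer not in pr.cdna
        assert revcomp(LAYOUT.p3_primer) not in pr.cdna
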