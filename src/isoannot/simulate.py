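"""Deterministic simulator for genomes, annotations, barcoded full-length
isoform reads, and pre-made splice-aware alignments with truth tables.

Every generator is fully determined by its seed, so tests and round-trip
checks can assert exact recovery.  The read simulator emulates the 10x
3' GEX v3.1 construct layout only (primers, cell barcode, UMI, polyA,
optional sample barcode) with a substitution-only error model; it does
not model PacBio error profiles, expression levels, ambient RNA or
doublets.

A note on truth cDNA: when a transcript's 3' end happens to end in
adenines, those bases are indistinguishable from the oligo-dT-captured
polyA tail, so ``cdna_recoverable`` in the truth table is defined as the
cDNA after applying the same maximal-tail trimming rule the processor
uses.  This is an identifiability limit of the construct, not of the
implementation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pysam

from .core import Annotation, ExonChain, GeneModel, TranscriptModel, revcomp
from .read_processing import (
    FULL_LENGTH,
    MISSING_3P,
    MISSING_5P,
    NO_POLYA,
    CcsRead,
    ReadLayout,
    trim_polya,
)

BASES = np.array(list("ACGT"))

DEFAULT_CATEGORY_MIX = {
    FULL_LENGTH: 0.8,
    MISSING_5P: 0.1,
    MISSING_3P: 0.05,
    NO_POLYA: 0.05,
}

CATEGORY_ORDER = (FULL_LENGTH, MISSING_5P, MISSING_3P, NO_POLYA)


@dataclass
class ReadTruth:
    """Ground truth for one simulated read."""

    read_id: str
    transcript_id: str
    gene_id: str
    cell_barcode: str          # as drawn (pre-error)
    umi: str
    cb_observed: str           # after planted sequencing errors
    umi_observed: str
    orientation: str           # sense | antisense
    category: str
    polya_len: int
    cdna_recoverable: str
    n_errors_cdna: int
    is_duplicate: bool = False
    duplicate_of: str = ""


def make_genome(n_chrom: int = 1, length: int = 100_000, gc: float = 0.5,
                seed: int = 0) -> Dict[str, str]:
    """Random genome: ``n_chrom`` contigs of ``length`` bp at the given GC
    content, named chr1..chrN."""
    if length < 1000:
        raise ValueError("contig length must be >= 1000")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return {
        f"chr{i + 1}": "".join(rng.choice(BASES, size=length, p=p))
        for i in range(n_chrom)
    }


def make_annotation(genome: Mapping[str, str], n_genes: int,
                    exons_per_gene: Tuple[int, int] = (1, 5),
                    exon_len: Tuple[int, int] = (120, 300),
                    intron_len: Tuple[int, int] = (80, 400),
                    utr3_len: Tuple[int, int] = (250, 500),
                    seed: int = 0, gene_prefix: str = "SYNG",
                    source: str = "ensembl", intergenic_gap: int = 200
                    ) -> Tuple[Annotation, Dict[str, int]]:
    """Place non-overlapping genes on both strands by rejection sampling.

    The strand-aware 3'-terminal exon of each gene is lengthened by a
    sampled 3'-UTR; the truth dict records that UTR length per gene.
    One transcript per gene.
    """
    rng = np.random.default_rng(seed)
    chroms = sorted(genome)
    occupied: Dict[str, List[Tuple[int, int]]] = {c: [] for c in chroms}
    genes: List[GeneModel] = []
    truth: Dict[str, int] = {}
    for i in range(n_genes):
        gid = f"{gene_prefix}{i + 1:05d}"
        strand = "+" if rng.random() < 0.5 else "-"
        n_exons = int(rng.integers(exons_per_gene[0], exons_per_gene[1] + 1))
        lens = [int(rng.integers(exon_len[0], exon_len[1] + 1))
                for _ in range(n_exons)]
        utr3 = int(rng.integers(utr3_len[0], utr3_len[1] + 1))
        if strand == "+":
            lens[-1] += utr3
        else:
            lens[0] += utr3
        gaps = [int(rng.integers(intron_len[0], intron_len[1] + 1))
                for _ in range(n_exons - 1)]
        footprint = sum(lens) + sum(gaps)
        placed = False
        for _attempt in range(300):
            chrom = chroms[int(rng.integers(len(chroms)))]
            limit = len(genome[chrom]) - footprint - intergenic_gap
            if limit <= intergenic_gap:
                continue
            start = int(rng.integers(intergenic_gap, limit))
            span = (start - intergenic_gap, start + footprint + intergenic_gap)
            if any(span[0] < e and s < span[1] for s, e in occupied[chrom]):
                continue
            occupied[chrom].append(span)
            exons = []
            pos = start
            for k, length in enumerate(lens):
                exons.append((pos, pos + length))
                pos += length
                if k < len(gaps):
                    pos += gaps[k]
            chain = ExonChain(chrom, strand, tuple(exons))
            tx = TranscriptModel(f"{gid}.t1", chain, source=source,
                                 gene_id=gid)
            genes.append(GeneModel(gid, chrom, strand, transcripts=[tx]))
            truth[gid] = utr3
            placed = True
            break
        if not placed:
            raise RuntimeError(
                f"could not place gene {i + 1}/{n_genes}; use a larger "
                f"genome or fewer genes")
    annot = Annotation(genes)
    annot.validate()
    return annot, truth


def truncate_utrs(annot: Annotation,
                  amount: Union[int, Tuple[int, int], Dict[str, int]] = 200,
                  seed: int = 0) -> Tuple[Annotation, Dict[str, int]]:
    """Shorten every gene's strand-aware 3'-terminal exon.

    ``amount`` is a fixed value, a (low, high) range sampled per gene, or
    an explicit per-gene dict.  Truncations that would consume a terminal
    exon are clamped to leave 1 nt; the truth dict records the amount
    actually applied per gene.
    """
    rng = np.random.default_rng(seed)
    out: List[GeneModel] = []
    truth: Dict[str, int] = {}
    for gene in annot.genes.values():
        if isinstance(amount, dict):
            amt = amount.get(gene.gene_id, 0)
        elif isinstance(amount, tuple):
            amt = int(rng.integers(amount[0], amount[1] + 1))
        else:
            amt = int(amount)
        # clamp so every transcript keeps >= 1 nt of terminal exon
        limit = amt
        for tx in gene.transcripts:
            term = tx.chain.exons[-1] if gene.strand == "+" \
                else tx.chain.exons[0]
            limit = min(limit, term[1] - term[0] - 1)
        applied = max(0, limit)
        truth[gene.gene_id] = applied
        new_txs = []
        for tx in gene.transcripts:
            exons = list(tx.chain.exons)
            if gene.strand == "+":
                s, e = exons[-1]
                exons[-1] = (s, e - applied)
            else:
                s, e = exons[0]
                exons[0] = (s + applied, e)
            new_txs.append(TranscriptModel(
                tx.transcript_id, ExonChain(tx.chrom, tx.strand, tuple(exons)),
                source=tx.source, gene_id=tx.gene_id, gene_name=tx.gene_name,
                cds=tx.cds))
        out.append(GeneModel(gene.gene_id, gene.chrom, gene.strand,
                             transcripts=new_txs, gene_name=gene.gene_name))
    return Annotation(out), truth


def spliced_sequence(chain: ExonChain, genome: Mapping[str, str]) -> str:
    """Sense-strand mRNA sequence of an exon chain."""
    seq = "".join(genome[chain.chrom][s:e] for s, e in chain.exons)
    return seq if chain.strand == "+" else revcomp(seq)


def generate_cell_barcodes(n: int, length: int = 16, min_hamming: int = 4,
                           rng: Optional[np.random.Generator] = None
                           ) -> List[str]:
    """Random barcodes at pairwise Hamming distance >= ``min_hamming`` so
    deduplication tests are unambiguous."""
    rng = rng or np.random.default_rng(0)
    barcodes: List[str] = []
    while len(barcodes) < n:
        cand = "".join(rng.choice(BASES, size=length))
        if all(sum(a != b for a, b in zip(cand, bc)) >= min_hamming
               for bc in barcodes):
            barcodes.append(cand)
    return barcodes


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(BASES, size=length))


def _mutate(seq: str, rng: np.random.Generator, rate: float
            ) -> Tuple[str, int]:
    """Uniform substitutions; returns (mutated sequence, error count)."""
    if rate <= 0 or not seq:
        return seq, 0
    mask = rng.random(len(seq)) < rate
    if not mask.any():
        return seq, 0
    chars = list(seq)
    for i in np.flatnonzero(mask):
        alternatives = [b for b in "ACGT" if b != chars[i]]
        chars[i] = alternatives[int(rng.integers(3))]
    return "".join(chars), int(mask.sum())


def _exact_counts(mix: Mapping[str, float], n: int) -> Dict[str, int]:
    """Largest-remainder apportionment of n reads over the category mix."""
    total = sum(mix.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"category mix must sum to 1, got {total}")
    raw = {c: mix.get(c, 0.0) * n for c in CATEGORY_ORDER}
    counts = {c: int(raw[c]) for c in CATEGORY_ORDER}
    short = n - sum(counts.values())
    by_rem = sorted(CATEGORY_ORDER, key=lambda c: (-(raw[c] - counts[c]), c))
    for c in by_rem[:short]:
        counts[c] += 1
    return counts


def simulate_scisoseq_reads(annot: Annotation, genome: Mapping[str, str],
                            layout: Optional[ReadLayout] = None,
                            n_cells: int = 50, reads_per_cell: int = 40,
                            error_rate: float = 0.0,
                            category_mix: Optional[Mapping[str, float]] = None,
                            n_duplicates: int = 0,
                            polya_len_range: Tuple[int, int] = (20, 60),
                            seed: int = 0
                            ) -> Tuple[List[CcsRead], List[ReadTruth]]:
    """Simulate barcoded full-length cDNA reads with a truth table.

    ``n_cells * reads_per_cell`` reads are produced in total; the last
    ``n_duplicates`` of them are PCR duplicates sharing (cell barcode,
    UMI, transcript) with an earlier full-length read.  Categories are
    planted with exact counts (largest-remainder over the mix), UMIs are
    drawn without replacement within a cell, and cell barcodes are
    pairwise Hamming-separated, so truth-table comparisons are exact at
    error rate 0.
    """
    layout = layout or ReadLayout()
    mix = dict(category_mix) if category_mix else dict(DEFAULT_CATEGORY_MIX)
    rng = np.random.default_rng(seed)
    n_total = n_cells * reads_per_cell
    if n_duplicates >= n_total:
        raise ValueError("n_duplicates must be smaller than the read count")
    n_primary = n_total - n_duplicates

    barcodes = generate_cell_barcodes(n_cells, layout.cb_len, rng=rng)
    txs = list(annot.transcripts())
    if not txs:
        raise ValueError("annotation has no transcripts")
    gene_of = {}
    for gene in annot.genes.values():
        for tx in gene.transcripts:
            gene_of[tx.transcript_id] = gene.gene_id
    cdna_cache = {tx.transcript_id: spliced_sequence(tx.chain, genome)
                  for tx in txs}

    counts = _exact_counts(mix, n_primary)
    categories: List[str] = []
    for c in CATEGORY_ORDER:
        categories.extend([c] * counts[c])
    rng.shuffle(categories)  # type: ignore[arg-type]

    used_umis: Dict[str, set] = {bc: set() for bc in barcodes}
    reads: List[CcsRead] = []
    truths: List[ReadTruth] = []

    def draw_umi(cb: str) -> str:
        while True:
            umi = _random_seq(rng, layout.umi_len)
            if umi not in used_umis[cb]:
                used_umis[cb].add(umi)
                return umi

    def build_read(read_id: str, category: str, cb: str, umi: str,
                   tx: TranscriptModel, duplicate_of: str = "") -> None:
        cdna = cdna_cache[tx.transcript_id]
        tail_len = int(rng.integers(polya_len_range[0],
                                    polya_len_range[1] + 1))
        if category == NO_POLYA:
            tail_len = 0
        cdna_obs, n_err_cdna = _mutate(cdna, rng, error_rate)
        tail_obs, _ = _mutate("A" * tail_len, rng, error_rate)
        rc_umi_obs, _ = _mutate(revcomp(umi), rng, error_rate)
        rc_cb_obs, _ = _mutate(revcomp(cb), rng, error_rate)
        p5_obs, _ = _mutate(layout.p5_primer, rng, error_rate)
        p3rc_obs, _ = _mutate(revcomp(layout.p3_primer), rng, error_rate)

        parts = []
        if layout.sample_barcode:
            sb_obs, _ = _mutate(layout.sample_barcode, rng, error_rate)
            parts.append(sb_obs)
        if category != MISSING_5P:
            parts.append(p5_obs)
        parts.append(cdna_obs)
        parts.append(tail_obs)
        if category != MISSING_3P:
            parts.extend([rc_umi_obs, rc_cb_obs, p3rc_obs])
            if layout.sample_barcode:
                sb3_obs, _ = _mutate(revcomp(layout.sample_barcode), rng,
                                     error_rate)
                parts.append(sb3_obs)
        sense = "".join(parts)
        orientation = "sense" if rng.random() < 0.5 else "antisense"
        sequence = sense if orientation == "sense" else revcomp(sense)

        recoverable, rec_tail = trim_polya(cdna_obs + tail_obs,
                                           layout.min_polya_len,
                                           layout.max_non_a)
        truths.append(ReadTruth(
            read_id=read_id, transcript_id=tx.transcript_id,
            gene_id=gene_of[tx.transcript_id], cell_barcode=cb, umi=umi,
            cb_observed=revcomp(rc_cb_obs), umi_observed=revcomp(rc_umi_obs),
            orientation=orientation, category=category, polya_len=rec_tail,
            cdna_recoverable=recoverable, n_errors_cdna=n_err_cdna,
            is_duplicate=bool(duplicate_of), duplicate_of=duplicate_of))
        reads.append(CcsRead(read_id, sequence))

    for i in range(n_primary):
        cb = barcodes[int(rng.integers(n_cells))]
        umi = draw_umi(cb)
        tx = txs[int(rng.integers(len(txs)))]
        build_read(f"read{i + 1:06d}", categories[i], cb, umi, tx)

    fl_primaries = [t for t in truths if t.category == FULL_LENGTH]
    if n_duplicates and not fl_primaries:
        raise ValueError("cannot plant duplicates without full-length reads")
    for j in range(n_duplicates):
        src = fl_primaries[int(rng.integers(len(fl_primaries)))]
        tx = next(t for t in txs if t.transcript_id == src.transcript_id)
        build_read(f"read{n_primary + j + 1:06d}", FULL_LENGTH,
                   src.cell_barcode, src.umi, tx, duplicate_of=src.read_id)
    return reads, truths


def simulate_alignments(truths: Sequence[ReadTruth], annot: Annotation,
                        genome: Mapping[str, str], path: str) -> int:
    """Write primary SAM records whose CIGARs encode the true exon chains.

    One record per truth row: M blocks split by N introns, NM set from
    the planted cDNA errors, CB/UB tags from the observed barcodes.  The
    sequence field is left empty ('*'); query length is implied by the
    CIGAR (substitution-only error model keeps them equal).  Returns the
    number of records written.
    """
    chains = {tx.transcript_id: tx.chain for tx in annot.transcripts()}
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": name, "LN": len(seq)}
               for name, seq in sorted(genome.items())],
    }
    tid_of = {sq["SN"]: i for i, sq in enumerate(header["SQ"])}
    n = 0
    with pysam.AlignmentFile(path, "w", header=header) as out:
        for truth in truths:
            chain = chains[truth.transcript_id]
            rec = pysam.AlignedSegment(out.header)
            rec.query_name = truth.read_id
            rec.flag = 16 if chain.strand == "-" else 0
            rec.reference_id = tid_of[chain.chrom]
            rec.reference_start = chain.start
            rec.mapping_quality = 60
            cigar = []
            for k, (s, e) in enumerate(chain.exons):
                cigar.append((0, e - s))
                if k < len(chain.exons) - 1:
                    cigar.append((3, chain.exons[k + 1][0] - e))
            rec.cigartuples = cigar
            rec.set_tag("NM", truth.n_errors_cdna)
            rec.set_tag("CB", truth.cb_observed)
            rec.set_tag("UB", truth.umi_observed)
            out.write(rec)
            n += 1
    return n


def write_truth_tsv(truths: Sequence[ReadTruth], path: str) -> None:
    cols = ["read_id", "transcript_id", "gene_id", "cell_barcode", "umi",
            "cb_observed", "umi_observed", "orientation", "category",
            "polya_len", "cdna_recoverable", "n_errors_cdna", "is_duplicate",
            "duplicate_of"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for t in truths:
            fh.write("\t".join(str(getattr(t, c)) for c in cols) + "\n")


def write_reads_fasta(reads: Sequence[CcsRead], path: str) -> None:
    with open(path, "w") as fh:
        for read in reads:
            fh.write(f">{read.read_id}\n{read.sequence}\n")
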