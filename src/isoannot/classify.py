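"""SQANTI-style structural classification of isoforms against a reference.

Each query transcript receives exactly one category, decided in a fixed
order:

1. **FSM** (full splice match): intron chain identical to some reference
   transcript of the same strand (mono-exon queries: reciprocal overlap
   with a mono-exon reference transcript).  Subcategorised by how far the
   5'/3' ends lie from the matched reference transcript.
2. **ISM** (incomplete splice match): intron chain is a consecutive
   sub-chain of a reference transcript's.
3. **FUSION**: the query's exons overlap the exonic spans of two or more
   distinct, mutually non-overlapping reference genes.
4. **NIC** (novel in catalog): all donors and acceptors are known for the
   overlapping gene, but the chain itself is new.
5. **NNC** (novel not in catalog): at least one donor or acceptor is
   absent from the gene's reference splice sites.  Subcategorised as
   intron retention when a query exon fully contains a reference intron.
6. **INTERGENIC**: no reference gene overlap at all.
7. **GENIC**: overlap without junction structure agreement (including
   mono-exon queries inside a gene).

Artifact filters flag intra-priming (genomic A-rich stretch immediately
downstream of the 3' end — the oligo-dT primer can anneal there instead
of a true polyA tail) and RT template switching (direct repeats flanking
a splice junction).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from .core import (
    Annotation,
    ExonChain,
    GeneModel,
    TranscriptModel,
    intersect_len,
    revcomp,
)

FSM = "FSM"
ISM = "ISM"
NIC = "NIC"
NNC = "NNC"
FUSION = "FUSION"
INTERGENIC = "INTERGENIC"
GENIC = "GENIC"

CATEGORIES = (FSM, ISM, NIC, NNC, FUSION, INTERGENIC, GENIC)

REFERENCE_MATCH = "reference_match"
ALT_3 = "alt_3"
ALT_5 = "alt_5"
ALT_3_AND_5 = "alt_3_and_5"

NOVEL_SITE = "novel_donor_or_acceptor"
INTRON_RETENTION = "intron_retention"

DEFAULT_END_TOL = 50
DEFAULT_IP_WINDOW = 20
DEFAULT_IP_A_FRAC = 0.6
DEFAULT_RT_REPEAT_LEN = 8
MONO_EXON_MIN_RECIP_OVERLAP = 0.5


@dataclass
class StructuralCall:
    """Category and subcategory of one isoform relative to the reference."""

    transcript_id: str
    category: str
    assigned_gene_ids: Tuple[str, ...] = ()
    matched_ref_transcript: Optional[str] = None
    fsm_subcategory: Optional[str] = None
    nnc_subcategory: Optional[str] = None
    diff_to_tss: Optional[int] = None
    diff_to_tts: Optional[int] = None


@dataclass
class FilterFlags:
    transcript_id: str
    intra_priming: bool = False
    rt_switching: bool = False

    @property
    def retained(self) -> bool:
        return not (self.intra_priming or self.rt_switching)


def _end_diffs(tx_chain: ExonChain, ref_chain: ExonChain) -> Tuple[int, int]:
    """Signed, strand-aware end differences vs a reference transcript.

    Positive diff_to_tss = query TSS downstream of the reference TSS;
    positive diff_to_tts = query TTS downstream (3'-extension).
    """
    if tx_chain.strand == "+":
        return tx_chain.start - ref_chain.start, tx_chain.end - ref_chain.end
    return ref_chain.end - tx_chain.end, ref_chain.start - tx_chain.start


def subclassify_fsm(diff_to_tss: int, diff_to_tts: int,
                    end_tol: int = DEFAULT_END_TOL) -> str:
    tss_off = abs(diff_to_tss) > end_tol
    tts_off = abs(diff_to_tts) > end_tol
    if tss_off and tts_off:
        return ALT_3_AND_5
    if tts_off:
        return ALT_3
    if tss_off:
        return ALT_5
    return REFERENCE_MATCH


def detect_intron_retention(tx: TranscriptModel, gene: GeneModel) -> bool:
    """True iff some query exon fully contains a reference intron of the
    gene, i.e. both flanking reference exons are overlapped by that same
    query exon."""
    for ref_tx in gene.transcripts:
        for istart, iend in ref_tx.chain.introns:
            for estart, eend in tx.chain.exons:
                if estart < istart and eend > iend:
                    return True
    return False


def _gene_splice_sites(gene: GeneModel) -> Tuple[set, set]:
    donors, acceptors = set(), set()
    for tx in gene.transcripts:
        donors.update(tx.chain.donor_sites())
        acceptors.update(tx.chain.acceptor_sites())
    return donors, acceptors


def _best_ref_match(tx: TranscriptModel, candidates: List[TranscriptModel]
                    ) -> Tuple[TranscriptModel, int, int]:
    best = None
    for ref_tx in candidates:
        d5, d3 = _end_diffs(tx.chain, ref_tx.chain)
        key = (abs(d5) + abs(d3), ref_tx.transcript_id)
        if best is None or key < best[0]:
            best = (key, ref_tx, d5, d3)
    assert best is not None
    return best[1], best[2], best[3]


def _is_consecutive_subchain(sub: Tuple, full: Tuple) -> bool:
    if not sub or len(sub) > len(full):
        return False
    for i in range(len(full) - len(sub) + 1):
        if full[i:i + len(sub)] == sub:
            return True
    return False


def classify_isoform(tx: TranscriptModel, ref: Annotation,
                     end_tol: int = DEFAULT_END_TOL) -> StructuralCall:
    """Assign one structural category to ``tx`` against ``ref``.

    Genes on the same strand as the query take priority; opposite-strand
    overlap only prevents an INTERGENIC call (yielding GENIC).
    """
    chain = tx.chain
    same = ref.query(chain.chrom, chain.start, chain.end, strand=chain.strand)
    other = [g for g in ref.query(chain.chrom, chain.start, chain.end)
             if g.strand != chain.strand]

    # (1) FSM
    if not chain.is_mono_exon:
        for gene in same:
            matches = [t for t in gene.transcripts
                       if t.chain.introns == chain.introns
                       and not t.chain.is_mono_exon]
            if matches:
                ref_tx, d5, d3 = _best_ref_match(tx, matches)
                return StructuralCall(
                    tx.transcript_id, FSM, (gene.gene_id,),
                    matched_ref_transcript=ref_tx.transcript_id,
                    fsm_subcategory=subclassify_fsm(d5, d3, end_tol),
                    diff_to_tss=d5, diff_to_tts=d3)
    else:
        for gene in same:
            matches = [t for t in gene.transcripts if t.chain.is_mono_exon
                       and _recip_overlap(t.chain.span, chain.span)
                       >= MONO_EXON_MIN_RECIP_OVERLAP]
            if matches:
                ref_tx, d5, d3 = _best_ref_match(tx, matches)
                return StructuralCall(
                    tx.transcript_id, FSM, (gene.gene_id,),
                    matched_ref_transcript=ref_tx.transcript_id,
                    fsm_subcategory=subclassify_fsm(d5, d3, end_tol),
                    diff_to_tss=d5, diff_to_tts=d3)

    # (2) ISM
    if not chain.is_mono_exon:
        for gene in same:
            matches = [t for t in gene.transcripts
                       if _is_consecutive_subchain(chain.introns,
                                                   t.chain.introns)]
            if matches:
                ref_tx, d5, d3 = _best_ref_match(tx, matches)
                return StructuralCall(
                    tx.transcript_id, ISM, (gene.gene_id,),
                    matched_ref_transcript=ref_tx.transcript_id,
                    diff_to_tss=d5, diff_to_tts=d3)

    # (3) FUSION: exonic overlap with >= 2 mutually non-overlapping genes
    exonic_hits = [g for g in same
                   if intersect_len(chain.exons, g.exonic_intervals()) > 0]
    if len(exonic_hits) >= 2:
        spans = [g.span for g in exonic_hits]
        disjoint = any(
            spans[i][1] <= spans[j][0] or spans[j][1] <= spans[i][0]
            for i in range(len(spans)) for j in range(i + 1, len(spans)))
        if disjoint:
            return StructuralCall(
                tx.transcript_id, FUSION,
                tuple(g.gene_id for g in exonic_hits))

    # (4)/(5) NIC / NNC against the best-overlapping same-strand gene
    if not chain.is_mono_exon and exonic_hits:
        gene = max(exonic_hits,
                   key=lambda g: (intersect_len(chain.exons,
                                                g.exonic_intervals()),
                                  g.gene_id))
        donors, acceptors = _gene_splice_sites(gene)
        novel = [d for d in chain.donor_sites() if d not in donors] + \
                [a for a in chain.acceptor_sites() if a not in acceptors]
        retained = detect_intron_retention(tx, gene)
        if not novel and not retained:
            return StructuralCall(tx.transcript_id, NIC, (gene.gene_id,))
        # intron retention counts as not-in-catalog even when the remaining
        # junctions reuse known sites; it takes subcategory priority
        sub = INTRON_RETENTION if retained else NOVEL_SITE
        return StructuralCall(tx.transcript_id, NNC, (gene.gene_id,),
                              nnc_subcategory=sub)

    # (6) INTERGENIC / (7) GENIC
    if not same and not other:
        return StructuralCall(tx.transcript_id, INTERGENIC, ())
    return StructuralCall(tx.transcript_id, GENIC,
                          tuple(g.gene_id for g in same))


def _recip_overlap(a: Tuple[int, int], b: Tuple[int, int]) -> float:
    ov = min(a[1], b[1]) - max(a[0], b[0])
    if ov <= 0:
        return 0.0
    return min(ov / (a[1] - a[0]), ov / (b[1] - b[0]))


def classify_annotation(txs: Iterable[TranscriptModel], ref: Annotation,
                        end_tol: int = DEFAULT_END_TOL
                        ) -> List[StructuralCall]:
    return [classify_isoform(tx, ref, end_tol) for tx in txs]


def intra_priming_flag(tx: TranscriptModel, genome: Mapping[str, str],
                       window: int = DEFAULT_IP_WINDOW,
                       a_frac: float = DEFAULT_IP_A_FRAC) -> bool:
    """True iff the genomic window immediately downstream (strand-aware)
    of the transcript 3' end is A-rich on the transcript strand.

    A window truncated by the contig end is evaluated over the available
    bases; an empty window is never flagged.
    """
    seq = genome[tx.chrom]
    if tx.strand == "+":
        segment = seq[tx.chain.end:tx.chain.end + window]
        a_count = segment.upper().count("A")
    else:
        start = max(0, tx.chain.start - window)
        segment = seq[start:tx.chain.start]
        a_count = segment.upper().count("T")  # A on the transcript strand
    if not segment:
        return False
    return a_count / len(segment) >= a_frac


def rt_switching_flag(junction: Tuple[str, int, int, str],
                      genome: Mapping[str, str],
                      repeat_len: int = DEFAULT_RT_REPEAT_LEN) -> bool:
    """Direct-repeat test for RT template switching at one junction.

    ``junction`` is (chrom, intron_start, intron_end, strand).  The
    repeat_len nt of exonic sequence ending at the donor site are
    compared with the repeat_len nt of intronic sequence ending at the
    acceptor's upstream flank; equality marks a template-switch artifact.
    """
    if repeat_len < 4:
        raise ValueError("repeat_len must be >= 4")
    chrom, istart, iend, strand = junction
    seq = genome[chrom]
    if istart - repeat_len < 0 or iend + repeat_len > len(seq):
        return False
    if strand == "+":
        donor_flank = seq[istart - repeat_len:istart]
        acceptor_flank = seq[iend - repeat_len:iend]
    else:
        donor_flank = seq[iend:iend + repeat_len]
        acceptor_flank = seq[istart:istart + repeat_len]
    return donor_flank.upper() == acceptor_flank.upper()


def compute_filter_flags(tx: TranscriptModel, genome: Mapping[str, str],
                         window: int = DEFAULT_IP_WINDOW,
                         a_frac: float = DEFAULT_IP_A_FRAC,
                         repeat_len: int = DEFAULT_RT_REPEAT_LEN
                         ) -> FilterFlags:
    rts = any(
        rt_switching_flag((tx.chrom, istart, iend, tx.strand), genome,
                          repeat_len)
        for istart, iend in tx.chain.introns)
    return FilterFlags(tx.transcript_id,
                       intra_priming=intra_priming_flag(tx, genome, window,
                                                        a_frac),
                       rt_switching=rts)


@dataclass
class FilterReport:
    retained: List[TranscriptModel]
    removed: List[TranscriptModel]
    removals_by_category: Counter = field(default_factory=Counter)
    fsm_exempted: int = 0


def filter_isoforms(txs: Sequence[TranscriptModel],
                    calls: Mapping[str, StructuralCall],
                    flags: Mapping[str, FilterFlags],
                    exempt_fsm_from_intra_priming: bool = True
                    ) -> FilterReport:
    """Remove artifact-flagged transcripts.

    A transcript flagged for RT switching is always removed; one flagged
    only for intra-priming is removed unless it is an FSM and the FSM
    exemption is on (an FSM matches an annotated model, so a genomic
    A-stretch there is weak evidence of artifact — removing such models
    would delete genuinely annotated genes).
    """
    report = FilterReport(retained=[], removed=[])
    for tx in txs:
        call = calls[tx.transcript_id]
        flag = flags[tx.transcript_id]
        ip = flag.intra_priming
        if ip and exempt_fsm_from_intra_priming and call.category == FSM:
            ip = False
            report.fsm_exempted += 1
        if flag.rt_switching or ip:
            report.removed.append(tx)
            report.removals_by_category[call.category] += 1
        else:
            report.retained.append(tx)
    return report


def classification_summary(calls: Sequence[StructuralCall]) -> pd.DataFrame:
    """Per-category and per-subcategory proportions (sum to 1 per level)."""
    if not calls:
        raise ValueError("classification_summary requires at least one call")
    rows = []
    n = len(calls)
    cat_counts = Counter(c.category for c in calls)
    for cat in CATEGORIES:
        if cat_counts[cat]:
            rows.append({"level": "category", "name": cat,
                         "count": cat_counts[cat],
                         "proportion": cat_counts[cat] / n})
    fsm_calls = [c for c in calls if c.category == FSM]
    for sub in (REFERENCE_MATCH, ALT_3, ALT_5, ALT_3_AND_5):
        k = sum(1 for c in fsm_calls if c.fsm_subcategory == sub)
        if k:
            rows.append({"level": "fsm_subcategory", "name": sub, "count": k,
                         "proportion": k / len(fsm_calls)})
    nnc_calls = [c for c in calls if c.category == NNC]
    for sub in (NOVEL_SITE, INTRON_RETENTION):
        k = sum(1 for c in nnc_calls if c.nnc_subcategory == sub)
        if k:
            rows.append({"level": "nnc_subcategory", "name": sub, "count": k,
                         "proportion": k / len(nnc_calls)})
    return pd.DataFrame(rows, columns=["level", "name", "count", "proportion"])


def calls_to_table(calls: Sequence[StructuralCall],
                   flags: Optional[Mapping[str, FilterFlags]] = None
                   ) -> pd.DataFrame:
    """One row per transcript: category, subcategories, gene ids, end
    diffs and artifact flags — the classification TSV payload."""
    rows = []
    for c in calls:
        flag = flags.get(c.transcript_id) if flags else None
        rows.append({
            "transcript_id": c.transcript_id,
            "category": c.category,
            "fsm_subcategory": c.fsm_subcategory or "",
            "nnc_subcategory": c.nnc_subcategory or "",
            "assigned_gene_ids": ",".join(c.assigned_gene_ids),
            "matched_ref_transcript": c.matched_ref_transcript or "",
            "diff_to_tss": c.diff_to_tss if c.diff_to_tss is not None else "",
            "diff_to_tts": c.diff_to_tts if c.diff_to_tts is not None else "",
            "intra_priming": flag.intra_priming if flag else "",
            "rt_switching": flag.rt_switching if flag else "",
        })
    return pd.DataFrame(rows)
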