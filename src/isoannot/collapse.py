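"""Collapse of aligned full-length reads into unique transcript models.

Reads are first filtered on alignment coverage (c) and identity (I) with
inclusive thresholds c >= 0.99 and I >= 0.95 by default, then grouped:

* multi-exon reads on the same chromosome and strand with identical
  intron chains (junctions equal within ``junction_tol``) become one
  transcript whose span is the widest member span and whose internal
  structure is the shared chain;
* mono-exon reads are clustered by single-linkage reciprocal overlap.

Transcript ids are assigned PB-style (``PB.<locus>.<n>``) in a fixed
deterministic order, so the result is invariant to input ordering.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .core import ExonChain, TranscriptModel, ValidationError

DEFAULT_MIN_COVERAGE = 0.99
DEFAULT_MIN_IDENTITY = 0.95

# CIGAR ops that consume query bases while aligned
_QUERY_ALIGNED_OPS = (0, 1, 7, 8)  # M, I, =, X
_CLIP_OPS = (4, 5)  # S, H

_MD_NUM = "0123456789"


@dataclass
class AlignedRead:
    """A mapped read carrying its exon chain and alignment metrics."""

    read_id: str
    chain: ExonChain
    coverage: float
    identity: float
    cell_barcode: Optional[str] = None
    umi: Optional[str] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.coverage <= 1.0:
            raise ValidationError(f"coverage out of [0,1]: {self.coverage}")
        if not 0.0 <= self.identity <= 1.0:
            raise ValidationError(f"identity out of [0,1]: {self.identity}")


def _edit_distance_from_md(md: str, cigartuples: Sequence[Tuple[int, int]]) -> int:
    """NM reconstruction: mismatches counted from MD, plus indel lengths
    from the CIGAR (introns excluded by construction)."""
    mismatches = 0
    i = 0
    while i < len(md):
        ch = md[i]
        if ch in _MD_NUM:
            i += 1
        elif ch == "^":  # deletion run: letters follow, already in CIGAR D
            i += 1
            while i < len(md) and md[i] not in _MD_NUM:
                i += 1
        else:
            mismatches += 1
            i += 1
    indels = sum(length for op, length in cigartuples if op in (1, 2))
    return mismatches + indels


def compute_alignment_metrics(rec, require_nm: bool = True
                              ) -> Tuple[float, float]:
    """Coverage and identity of one pysam alignment record.

    coverage = aligned query bases / full query length (soft and hard
    clips count toward the denominator only); identity = (aligned query
    bases - edit distance) / aligned query bases, where the edit distance
    comes from the NM tag (introns excluded), falling back to MD + CIGAR
    when NM is absent.
    """
    cig = rec.cigartuples or ()
    aligned = sum(length for op, length in cig if op in _QUERY_ALIGNED_OPS)
    clipped = sum(length for op, length in cig if op in _CLIP_OPS)
    full = aligned + clipped
    if aligned == 0 or full == 0:
        raise ValidationError(f"read {rec.query_name}: no aligned bases")
    if rec.query_sequence and rec.query_sequence != "*":
        soft = sum(length for op, length in cig if op == 4)
        if len(rec.query_sequence) != aligned + soft:
            raise ValidationError(
                f"read {rec.query_name}: CIGAR does not consume the stated "
                f"query length")
    if rec.has_tag("NM"):
        nm = int(rec.get_tag("NM"))
    elif rec.has_tag("MD"):
        nm = _edit_distance_from_md(rec.get_tag("MD"), cig)
    elif require_nm:
        raise ValidationError(
            f"read {rec.query_name}: neither NM nor MD tag present; "
            f"identity cannot be computed")
    else:
        nm = 0
    coverage = aligned / full
    identity = max(0.0, (aligned - nm) / aligned)
    return coverage, identity


def filter_alignments(reads: Iterable[AlignedRead],
                      c_min: float = DEFAULT_MIN_COVERAGE,
                      i_min: float = DEFAULT_MIN_IDENTITY
                      ) -> Tuple[List[AlignedRead], int]:
    """Keep reads with coverage >= c_min and identity >= i_min (inclusive).

    Returns (passing reads, rejected count).
    """
    passing, rejected = [], 0
    for read in reads:
        if read.coverage >= c_min and read.identity >= i_min:
            passing.append(read)
        else:
            rejected += 1
    return passing, rejected


def _reciprocal_overlap(a: Tuple[int, int], b: Tuple[int, int]) -> float:
    ov = min(a[1], b[1]) - max(a[0], b[0])
    if ov <= 0:
        return 0.0
    return min(ov / (a[1] - a[0]), ov / (b[1] - b[0]))


def _junctions_match(a: Tuple[Tuple[int, int], ...],
                     b: Tuple[Tuple[int, int], ...], tol: int) -> bool:
    if len(a) != len(b):
        return False
    return all(abs(x[0] - y[0]) <= tol and abs(x[1] - y[1]) <= tol
               for x, y in zip(a, b))


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def _group_multi_exon(reads: List[AlignedRead], tol: int
                      ) -> List[List[AlignedRead]]:
    if tol == 0:
        by_chain: Dict[tuple, List[AlignedRead]] = {}
        for read in reads:
            key = (read.chain.chrom, read.chain.strand, read.chain.introns)
            by_chain.setdefault(key, []).append(read)
        return [by_chain[k] for k in sorted(by_chain)]
    # tolerant mode: single linkage over near-identical junction chains
    uf = _UnionFind(len(reads))
    for i in range(len(reads)):
        for j in range(i + 1, len(reads)):
            a, b = reads[i].chain, reads[j].chain
            if a.chrom == b.chrom and a.strand == b.strand and \
                    _junctions_match(a.introns, b.introns, tol):
                uf.union(i, j)
    groups: Dict[int, List[AlignedRead]] = {}
    for i, read in enumerate(reads):
        groups.setdefault(uf.find(i), []).append(read)
    return [groups[k] for k in sorted(groups)]


def _group_mono_exon(reads: List[AlignedRead], min_overlap: float
                     ) -> List[List[AlignedRead]]:
    by_loc: Dict[Tuple[str, str], List[AlignedRead]] = {}
    for read in reads:
        by_loc.setdefault((read.chain.chrom, read.chain.strand), []).append(read)
    out: List[List[AlignedRead]] = []
    for key in sorted(by_loc):
        members = sorted(by_loc[key],
                         key=lambda r: (r.chain.start, r.chain.end, r.read_id))
        uf = _UnionFind(len(members))
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                if _reciprocal_overlap(members[i].chain.span,
                                       members[j].chain.span) >= min_overlap:
                    uf.union(i, j)
        groups: Dict[int, List[AlignedRead]] = {}
        for i, read in enumerate(members):
            groups.setdefault(uf.find(i), []).append(read)
        out.extend(groups[k] for k in sorted(groups))
    return out


def _model_from_group(group: List[AlignedRead]) -> Tuple[ExonChain, Tuple[str, ...]]:
    chains = [r.chain for r in group]
    chrom = chains[0].chrom
    strand = chains[0].strand
    assert all(c.chrom == chrom and c.strand == strand for c in chains), \
        "collapse group spans chromosomes"
    start = min(c.start for c in chains)
    end = max(c.end for c in chains)
    introns = chains[0].introns
    if introns:
        exons = [(start, introns[0][0])]
        exons += [(introns[k][1], introns[k + 1][0])
                  for k in range(len(introns) - 1)]
        exons.append((introns[-1][1], end))
    else:
        exons = [(start, end)]
    support = tuple(sorted(r.read_id for r in group))
    return ExonChain(chrom, strand, tuple(exons)), support


def collapse_isoforms(reads: Sequence[AlignedRead], junction_tol: int = 0,
                      mono_exon_min_overlap: float = 0.5
                      ) -> List[TranscriptModel]:
    """Collapse filtered reads into unique transcript models.

    The result is deterministic and independent of input order:
    transcripts are sorted by (chrom, start, chain), grouped into loci by
    same-strand exonic overlap, and numbered ``PB.<locus>.<n>``.
    """
    reads = sorted(reads, key=lambda r: (r.chain.chrom, r.chain.start,
                                         r.chain.end, r.read_id))
    multi = [r for r in reads if not r.chain.is_mono_exon]
    mono = [r for r in reads if r.chain.is_mono_exon]
    groups = _group_multi_exon(multi, junction_tol) + \
        _group_mono_exon(mono, mono_exon_min_overlap)
    models = [_model_from_group(g) for g in groups]
    models.sort(key=lambda m: (m[0].chrom, m[0].start, m[0].end, m[0].exons))

    # locus assignment: connected components of same-strand exonic overlap
    uf = _UnionFind(len(models))
    for i in range(len(models)):
        for j in range(i + 1, len(models)):
            a, b = models[i][0], models[j][0]
            if a.chrom != b.chrom:
                continue
            if a.strand == b.strand and a.exon_overlap_len(b) > 0:
                uf.union(i, j)
    locus_of: Dict[int, int] = {}
    next_locus = 0
    out: List[TranscriptModel] = []
    counters: Dict[int, int] = {}
    for i, (chain, support) in enumerate(models):
        root = uf.find(i)
        if root not in locus_of:
            next_locus += 1
            locus_of[root] = next_locus
        locus = locus_of[root]
        counters[locus] = counters.get(locus, 0) + 1
        out.append(TranscriptModel(
            transcript_id=f"PB.{locus}.{counters[locus]}",
            chain=chain, source="isoseq", support=support))
    return out
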