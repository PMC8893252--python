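"""Core genomic data model.

All coordinates held in memory are 0-based, half-open, in genomic
ascending order regardless of strand.  Strand is interpreted only where a
5'/3' semantic is needed (end shifts, polyA windows, donor/acceptor
sites).  On-disk conventions (GTF 1-based inclusive, BED12 0-based
half-open with block offsets) are converted in :mod:`isoannot.io_formats`
and nowhere else.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, Tuple

from intervaltree import IntervalTree

STRANDS = ("+", "-")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


class ValidationError(ValueError):
    """An in-memory object violates a structural invariant."""


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (ACGTN, case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def merge_intervals(intervals: Iterable[Tuple[int, int]]) -> List[Tuple[int, int]]:
    """Union of half-open intervals, returned sorted and disjoint."""
    ivs = sorted(intervals)
    out: List[Tuple[int, int]] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def intersect_len(a: Sequence[Tuple[int, int]], b: Sequence[Tuple[int, int]]) -> int:
    """Total overlap in bp between two interval sets (need not be disjoint)."""
    a = merge_intervals(a)
    b = merge_intervals(b)
    total = 0
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s < e:
            total += e - s
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return total


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval with strand."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("chrom must be non-empty")
        if not self.start < self.end:
            raise ValidationError(
                f"interval start must be < end, got ({self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise ValidationError(f"strand must be + or -, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap_len(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class ExonChain:
    """Strand-aware ordered exon structure of one transcript.

    Exons are (start, end) half-open intervals in genomic ascending order;
    the gaps between consecutive exons are the introns.  The intron chain
    is the identity key used for isoform collapse and full-splice-match
    classification.
    """

    chrom: str
    strand: str
    exons: Tuple[Tuple[int, int], ...]

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("chrom must be non-empty")
        if self.strand not in STRANDS:
            raise ValidationError(f"strand must be + or -, got {self.strand!r}")
        if not self.exons:
            raise ValidationError("exon chain must contain at least one exon")
        object.__setattr__(self, "exons", tuple((int(s), int(e)) for s, e in self.exons))
        prev_end = None
        for s, e in self.exons:
            if not s < e:
                raise ValidationError(f"exon start must be < end, got ({s}, {e})")
            if prev_end is not None and s <= prev_end:
                raise ValidationError(
                    "exons must be sorted, non-overlapping, with introns >= 1 nt"
                )
            prev_end = e

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def span(self) -> Tuple[int, int]:
        return (self.start, self.end)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def introns(self) -> Tuple[Tuple[int, int], ...]:
        return tuple(
            (self.exons[i][1], self.exons[i + 1][0]) for i in range(len(self.exons) - 1)
        )

    @property
    def is_mono_exon(self) -> bool:
        return len(self.exons) == 1

    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def donor_sites(self) -> Tuple[int, ...]:
        """Genomic coordinates of splice donor sites (exon/intron boundary
        on the 5' side of each intron, in transcript orientation)."""
        if self.strand == "+":
            return tuple(i[0] for i in self.introns)
        return tuple(i[1] for i in self.introns)

    def acceptor_sites(self) -> Tuple[int, ...]:
        if self.strand == "+":
            return tuple(i[1] for i in self.introns)
        return tuple(i[0] for i in self.introns)

    def tss(self) -> int:
        """Transcription start site (strand-aware point coordinate)."""
        return self.start if self.strand == "+" else self.end

    def tts(self) -> int:
        """Transcription termination site (strand-aware point coordinate)."""
        return self.end if self.strand == "+" else self.start

    def exon_overlap_len(self, other: "ExonChain") -> int:
        if self.chrom != other.chrom:
            return 0
        return intersect_len(self.exons, other.exons)


@dataclass
class TranscriptModel:
    """A transcript: one exon chain plus provenance.

    ``source`` distinguishes reference models (``ensembl``) from models
    built out of long reads (``isoseq``).  ``support`` lists the read ids
    that were collapsed into this model (isoseq transcripts only).
    ``cds`` carries reference CDS intervals through merges verbatim; no
    CDS is ever inferred for isoseq transcripts.
    """

    transcript_id: str
    chain: ExonChain
    source: str = "isoseq"
    gene_id: Optional[str] = None
    gene_name: Optional[str] = None
    support: Tuple[str, ...] = ()
    cds: Tuple[Tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.source not in ("ensembl", "isoseq"):
            raise ValidationError(f"unknown source {self.source!r}")
        self.support = tuple(self.support)
        self.cds = tuple((int(s), int(e)) for s, e in self.cds)

    @property
    def chrom(self) -> str:
        return self.chain.chrom

    @property
    def strand(self) -> str:
        return self.chain.strand

    def signature(self) -> tuple:
        return (self.transcript_id, self.chain.chrom, self.chain.strand,
                self.chain.exons, self.source, self.cds)


@dataclass
class GeneModel:
    """Transcripts united under a single gene model (same chrom/strand)."""

    gene_id: str
    chrom: str
    strand: str
    transcripts: List[TranscriptModel] = field(default_factory=list)
    gene_name: Optional[str] = None

    def __post_init__(self) -> None:
        for tx in self.transcripts:
            if tx.chrom != self.chrom or tx.strand != self.strand:
                raise ValidationError(
                    f"transcript {tx.transcript_id} does not match gene "
                    f"{self.gene_id} chrom/strand"
                )

    @property
    def span(self) -> Tuple[int, int]:
        if not self.transcripts:
            raise ValidationError(f"gene {self.gene_id} has no transcripts")
        return (min(t.chain.start for t in self.transcripts),
                max(t.chain.end for t in self.transcripts))

    @property
    def start(self) -> int:
        return self.span[0]

    @property
    def end(self) -> int:
        return self.span[1]

    def exonic_intervals(self) -> List[Tuple[int, int]]:
        ivs: List[Tuple[int, int]] = []
        for tx in self.transcripts:
            ivs.extend(tx.chain.exons)
        return merge_intervals(ivs)

    def longest_transcript(self) -> TranscriptModel:
        """Transcript with the greatest summed exon length (ties broken by id)."""
        return min(self.transcripts,
                   key=lambda t: (-t.chain.exonic_length(), t.transcript_id))


class Annotation:
    """A queryable collection of gene models.

    Gene ids are unique; transcript ids are unique across the whole
    annotation.  An interval index per chromosome supports overlap
    queries against gene spans.
    """

    def __init__(self, genes: Iterable[GeneModel] = ()) -> None:
        self._genes: Dict[str, GeneModel] = {}
        self._index: Optional[Dict[str, IntervalTree]] = None
        for g in genes:
            self.add_gene(g)

    def add_gene(self, gene: GeneModel) -> None:
        if gene.gene_id in self._genes:
            raise ValidationError(f"duplicate gene_id {gene.gene_id!r}")
        self._genes[gene.gene_id] = gene
        self._index = None

    @property
    def genes(self) -> Dict[str, GeneModel]:
        return self._genes

    def __len__(self) -> int:
        return len(self._genes)

    def __iter__(self) -> Iterator[GeneModel]:
        return iter(sorted(self._genes.values(),
                           key=lambda g: (g.chrom, g.start, g.gene_id)))

    def transcripts(self) -> Iterator[TranscriptModel]:
        for gene in self:
            for tx in sorted(gene.transcripts,
                             key=lambda t: (t.chain.start, t.transcript_id)):
                yield tx

    @property
    def n_transcripts(self) -> int:
        return sum(len(g.transcripts) for g in self._genes.values())

    def chroms(self) -> List[str]:
        return sorted({g.chrom for g in self._genes.values()})

    def validate(self) -> None:
        seen: set = set()
        for g in self._genes.values():
            g.span  # raises when empty
            for tx in g.transcripts:
                if tx.transcript_id in seen:
                    raise ValidationError(
                        f"duplicate transcript_id {tx.transcript_id!r}")
                seen.add(tx.transcript_id)

    def _build_index(self) -> Dict[str, IntervalTree]:
        if self._index is None:
            idx: Dict[str, IntervalTree] = {}
            for g in self._genes.values():
                s, e = g.span
                idx.setdefault(g.chrom, IntervalTree()).addi(s, e, g)
            self._index = idx
        return self._index

    def query(self, chrom: str, start: int, end: int,
              strand: Optional[str] = None) -> List[GeneModel]:
        """Genes whose span overlaps [start, end); optionally strand-filtered."""
        idx = self._build_index()
        if chrom not in idx:
            return []
        hits = [iv.data for iv in idx[chrom].overlap(start, end)]
        if strand is not None:
            hits = [g for g in hits if g.strand == strand]
        return sorted(hits, key=lambda g: (g.start, g.gene_id))

    def signature(self) -> tuple:
        """Structural identity: ids, names, chains, sources, CDS.

        Read support is deliberately excluded — it does not survive
        serialisation round trips.
        """
        return tuple(
            (g.gene_id, g.gene_name, g.chrom, g.strand,
             tuple(sorted(t.signature() for t in g.transcripts)))
            for g in self
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Annotation):
            return NotImplemented
        return self.signature() == other.signature()

    def __repr__(self) -> str:
        return f"Annotation({len(self)} genes, {self.n_transcripts} transcripts)"
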