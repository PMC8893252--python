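"""Readers and writers for GTF, BED12 and SAM.

This is the single module that converts between on-disk coordinate
conventions and the in-memory one (0-based half-open):

* GTF (Ensembl dialect): 1-based, fully inclusive.
* BED12 (TAMA dialect): 0-based half-open, exon blocks as offsets, the
  name field is ``gene_id;transcript_id``.
* SAM: 1-based positions via pysam, exposed 0-based by pysam itself.

Writers emit records in a fixed deterministic order so that two writes of
the same annotation are byte-identical.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, Tuple, Union

import pysam

from .core import (
    Annotation,
    ExonChain,
    GeneModel,
    TranscriptModel,
    ValidationError,
)

PathLike = Union[str, Path]

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"\s*;')

# source column values recognised as provenance tags; anything else maps
# to the caller-supplied default
_KNOWN_SOURCES = ("ensembl", "isoseq")


class GtfParseError(ValueError):
    """A GTF line could not be parsed; message names the line number."""


class Bed12ParseError(ValueError):
    """A BED12 line could not be parsed."""


def _parse_attributes(attr_field: str, lineno: int) -> Dict[str, str]:
    attrs = dict(_ATTR_RE.findall(attr_field))
    if not attrs:
        raise GtfParseError(
            f"line {lineno}: malformed attribute field {attr_field!r}")
    return attrs


def read_gtf(path: PathLike, default_source: str = "ensembl") -> Annotation:
    """Read an Ensembl-dialect GTF into an :class:`Annotation`.

    Only ``exon`` and ``CDS`` features are consumed; ``gene`` and
    ``transcript`` container lines are ignored (they are reconstructed
    from the exons).  The GTF ``source`` column is kept when it is one of
    the provenance tags (``ensembl``/``isoseq``), otherwise
    ``default_source`` is used.
    """
    exons: Dict[str, List[Tuple[int, int]]] = {}
    cds: Dict[str, List[Tuple[int, int]]] = {}
    meta: Dict[str, Tuple[str, str, str, Optional[str], str]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 8:
                raise GtfParseError(
                    f"line {lineno}: expected >= 8 tab-separated fields, "
                    f"got {len(fields)}")
            chrom, source, feature, start_s, end_s, _score, strand, _frame = \
                fields[:8]
            if feature not in ("exon", "CDS"):
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise GtfParseError(
                    f"line {lineno}: non-integer coordinates") from exc
            if end1 < start1:
                raise ValidationError(
                    f"line {lineno}: feature end {end1} < start {start1}")
            attrs = _parse_attributes(fields[8] if len(fields) > 8 else "",
                                      lineno)
            if "gene_id" not in attrs or "transcript_id" not in attrs:
                raise GtfParseError(
                    f"line {lineno}: missing gene_id or transcript_id attribute")
            tx_id = attrs["transcript_id"]
            # GTF is 1-based inclusive -> 0-based half-open
            iv = (start1 - 1, end1)
            tx_source = source if source in _KNOWN_SOURCES else default_source
            meta.setdefault(tx_id, (attrs["gene_id"], chrom, strand,
                                    attrs.get("gene_name"), tx_source))
            if meta[tx_id][1] != chrom or meta[tx_id][2] != strand:
                raise ValidationError(
                    f"line {lineno}: transcript {tx_id} spans multiple "
                    f"chromosomes or strands")
            if feature == "exon":
                exons.setdefault(tx_id, []).append(iv)
            else:
                cds.setdefault(tx_id, []).append(iv)

    genes: Dict[str, GeneModel] = {}
    for tx_id, (gene_id, chrom, strand, gene_name, tx_source) in meta.items():
        if tx_id not in exons:
            continue  # CDS-only transcript: nothing to model
        chain = ExonChain(chrom, strand, tuple(sorted(exons[tx_id])))
        tx = TranscriptModel(tx_id, chain, source=tx_source, gene_id=gene_id,
                             gene_name=gene_name,
                             cds=tuple(sorted(cds.get(tx_id, []))))
        if gene_id not in genes:
            genes[gene_id] = GeneModel(gene_id, chrom, strand,
                                       gene_name=gene_name)
        genes[gene_id].transcripts.append(tx)
        if genes[gene_id].gene_name is None and gene_name is not None:
            genes[gene_id].gene_name = gene_name
    for g in genes.values():
        g.transcripts.sort(key=lambda t: (t.chain.start, t.transcript_id))
    annot = Annotation(genes.values())
    annot.validate()
    return annot


def _gtf_line(chrom: str, source: str, feature: str, start: int, end: int,
              strand: str, gene_id: str, tx_id: str,
              gene_name: Optional[str]) -> str:
    attrs = f'gene_id "{gene_id}"; transcript_id "{tx_id}";'
    if gene_name:
        attrs += f' gene_name "{gene_name}";'
    # 0-based half-open -> 1-based inclusive
    return (f"{chrom}\t{source}\t{feature}\t{start + 1}\t{end}\t.\t{strand}"
            f"\t.\t{attrs}")


def write_gtf(annot: Annotation, path: PathLike) -> None:
    """Write an annotation as Ensembl-dialect GTF (exon + CDS lines).

    Records are ordered by (chrom, gene start, gene_id, transcript start,
    transcript_id, exon start), giving byte-identical output for repeated
    writes of the same annotation.
    """
    lines: List[str] = []
    for gene in annot:
        for tx in sorted(gene.transcripts,
                         key=lambda t: (t.chain.start, t.transcript_id)):
            name = tx.gene_name or gene.gene_name
            for s, e in tx.chain.exons:
                lines.append(_gtf_line(gene.chrom, tx.source, "exon", s, e,
                                       gene.strand, gene.gene_id,
                                       tx.transcript_id, name))
            for s, e in tx.cds:
                lines.append(_gtf_line(gene.chrom, tx.source, "CDS", s, e,
                                       gene.strand, gene.gene_id,
                                       tx.transcript_id, name))
    with open(path, "w") as fh:
        fh.write("\n".join(lines))
        if lines:
            fh.write("\n")


@dataclass(frozen=True)
class Bed12Record:
    """One BED12 line in the TAMA dialect (name = ``gene_id;transcript_id``)."""

    chrom: str
    start: int
    end: int
    name: str
    score: int
    strand: str
    thick_start: int
    thick_end: int
    item_rgb: str
    block_count: int
    block_sizes: Tuple[int, ...]
    block_starts: Tuple[int, ...]

    def to_line(self) -> str:
        sizes = ",".join(str(x) for x in self.block_sizes)
        starts = ",".join(str(x) for x in self.block_starts)
        return "\t".join(str(x) for x in (
            self.chrom, self.start, self.end, self.name, self.score,
            self.strand, self.thick_start, self.thick_end, self.item_rgb,
            self.block_count, sizes, starts))

    @classmethod
    def from_line(cls, line: str, lineno: int = 0) -> "Bed12Record":
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 12:
            raise Bed12ParseError(
                f"line {lineno}: expected 12 fields, got {len(fields)}")
        try:
            return cls(
                chrom=fields[0], start=int(fields[1]), end=int(fields[2]),
                name=fields[3], score=int(fields[4]), strand=fields[5],
                thick_start=int(fields[6]), thick_end=int(fields[7]),
                item_rgb=fields[8], block_count=int(fields[9]),
                block_sizes=tuple(int(x) for x in fields[10].rstrip(",").split(",")),
                block_starts=tuple(int(x) for x in fields[11].rstrip(",").split(",")),
            )
        except ValueError as exc:
            raise Bed12ParseError(f"line {lineno}: {exc}") from exc

    def split_name(self) -> Tuple[str, str]:
        if self.name.count(";") != 1:
            raise Bed12ParseError(
                f"name field {self.name!r} must contain exactly one ';' "
                f"separating gene_id from transcript_id")
        gene_id, tx_id = self.name.split(";")
        return gene_id, tx_id


def annotation_to_bed12(annot: Annotation) -> List[Bed12Record]:
    """One BED12 record per transcript, TAMA-style.

    Score is fixed at 40 and thickStart/thickEnd default to the transcript
    span when the transcript carries no CDS (TAMA-like defaults).  Gene
    names and read support are not representable in BED12.
    """
    records: List[Bed12Record] = []
    for gene in annot:
        for tx in sorted(gene.transcripts,
                         key=lambda t: (t.chain.start, t.transcript_id)):
            exons = tx.chain.exons
            start = exons[0][0]
            end = exons[-1][1]
            if tx.cds:
                thick = (min(s for s, _ in tx.cds), max(e for _, e in tx.cds))
            else:
                thick = (start, end)
            records.append(Bed12Record(
                chrom=gene.chrom, start=start, end=end,
                name=f"{gene.gene_id};{tx.transcript_id}", score=40,
                strand=gene.strand, thick_start=thick[0], thick_end=thick[1],
                item_rgb="0", block_count=len(exons),
                block_sizes=tuple(e - s for s, e in exons),
                block_starts=tuple(s - start for s, _ in exons)))
    records.sort(key=lambda r: (r.chrom, r.start, r.name))
    return records


def bed12_to_annotation(records: Iterable[Bed12Record],
                        source: str = "isoseq") -> Annotation:
    """Rebuild an annotation from TAMA-dialect BED12 records."""
    genes: Dict[str, GeneModel] = {}
    for rec in records:
        gene_id, tx_id = rec.split_name()
        if len(rec.block_sizes) != rec.block_count or \
                len(rec.block_starts) != rec.block_count:
            raise Bed12ParseError(
                f"record {rec.name}: blockCount {rec.block_count} does not "
                f"match block lists")
        exons = tuple((rec.start + off, rec.start + off + size)
                      for off, size in zip(rec.block_starts, rec.block_sizes))
        chain = ExonChain(rec.chrom, rec.strand, exons)
        tx = TranscriptModel(tx_id, chain, source=source, gene_id=gene_id)
        if gene_id not in genes:
            genes[gene_id] = GeneModel(gene_id, rec.chrom, rec.strand)
        genes[gene_id].transcripts.append(tx)
    for g in genes.values():
        g.transcripts.sort(key=lambda t: (t.chain.start, t.transcript_id))
    annot = Annotation(genes.values())
    annot.validate()
    return annot


def write_bed12(records: Sequence[Bed12Record], path: PathLike) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(rec.to_line() + "\n")


def read_bed12(path: PathLike) -> List[Bed12Record]:
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            records.append(Bed12Record.from_line(line, lineno))
    return records


def exon_chain_from_cigar(pos: int, cigartuples: Sequence[Tuple[int, int]],
                          chrom: str, strand: str) -> ExonChain:
    """Build the reference exon chain by splitting the alignment footprint
    at N (intron) operations.

    M/=/X and D consume reference within the current exon; N closes it.
    """
    exons: List[Tuple[int, int]] = []
    ref = pos
    exon_start = pos
    for op, length in cigartuples:
        if op in (0, 7, 8, 2):  # M, =, X, D consume reference
            ref += length
        elif op == 3:  # N: intron
            if ref > exon_start:
                exons.append((exon_start, ref))
            ref += length
            exon_start = ref
        # I, S, H, P consume no reference
    if ref > exon_start:
        exons.append((exon_start, ref))
    return ExonChain(chrom, strand, tuple(exons))


def parse_sam_alignments(path: PathLike,
                         require_tags: bool = True):
    """Yield :class:`~isoannot.collapse.AlignedRead` from a SAM/BAM file.

    Unmapped, secondary and supplementary records are skipped (counts are
    returned alongside).  Coverage and identity are populated from the
    CIGAR and the NM (or MD) tag.  Cell barcode and UMI are taken from the
    CB/UB tags when present.

    Returns ``(reads, skipped)`` where skipped is a dict of counts.
    """
    from .collapse import AlignedRead, compute_alignment_metrics

    reads: List = []
    skipped = {"unmapped": 0, "secondary": 0, "supplementary": 0}
    mode = "rb" if str(path).endswith(".bam") else "r"
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped:
                skipped["unmapped"] += 1
                continue
            if rec.is_secondary:
                skipped["secondary"] += 1
                continue
            if rec.is_supplementary:
                skipped["supplementary"] += 1
                continue
            strand = "-" if rec.is_reverse else "+"
            chain = exon_chain_from_cigar(rec.reference_start,
                                          rec.cigartuples or (),
                                          rec.reference_name, strand)
            cov, ident = compute_alignment_metrics(rec,
                                                   require_nm=require_tags)
            cb = rec.get_tag("CB") if rec.has_tag("CB") else None
            umi = rec.get_tag("UB") if rec.has_tag("UB") else None
            reads.append(AlignedRead(read_id=rec.query_name, chain=chain,
                                     coverage=cov, identity=ident,
                                     cell_barcode=cb, umi=umi))
    return reads, skipped


def read_fasta(path: PathLike) -> Dict[str, str]:
    """Plain FASTA -> dict of upper-case sequences (order preserved)."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Dict[str, str], path: PathLike, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
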