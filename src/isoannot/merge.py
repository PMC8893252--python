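"""Merging isoform-derived transcript models with a reference annotation.

Transcripts from both sources are pooled and genes are re-formed as
connected components of same-strand transcripts linked by at least 1 nt
of exonic overlap.  With ``dedup`` on, transcripts with identical exon
chains collapse to one copy, keeping the reference (ensembl-source) one.
Merged genes containing a reference transcript adopt its Ensembl gene id
and name; isoseq-only genes receive sequential novel ids.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from intervaltree import IntervalTree

from .core import (
    Annotation,
    GeneModel,
    TranscriptModel,
    ValidationError,
    intersect_len,
    merge_intervals,
)

NOVEL_GENE_FMT = "NOVELG_{:06d}"


@dataclass
class MergeReport:
    n_input_transcripts: int = 0
    n_output_transcripts: int = 0
    duplicates_removed: List[Tuple[str, str]] = field(default_factory=list)
    # (removed transcript_id, kept transcript_id)
    id_conflicts: List[Tuple[str, str, Tuple[str, ...]]] = field(
        default_factory=list)
    # (merged gene id, adopted ensembl id, other candidate ids)


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


def _dedup_transcripts(txs: List[TranscriptModel], report: MergeReport
                       ) -> List[TranscriptModel]:
    """Collapse identical exon chains; the ensembl-source copy wins, then
    the lexicographically smallest transcript id."""
    by_chain: Dict[tuple, TranscriptModel] = {}
    for tx in txs:
        key = (tx.chain.chrom, tx.chain.strand, tx.chain.exons)
        cur = by_chain.get(key)
        if cur is None:
            by_chain[key] = tx
            continue
        rank = lambda t: (0 if t.source == "ensembl" else 1, t.transcript_id)
        keep, drop = (cur, tx) if rank(cur) <= rank(tx) else (tx, cur)
        keep.support = tuple(sorted(set(keep.support) | set(drop.support)))
        by_chain[key] = keep
        report.duplicates_removed.append((drop.transcript_id,
                                          keep.transcript_id))
    return [by_chain[k] for k in sorted(by_chain)]


def merge_annotations(ensembl: Annotation, isoseq: Annotation,
                      dedup: bool = True
                      ) -> Tuple[Annotation, MergeReport]:
    """Pool two annotations and re-form gene models.

    Gene linkage requires exonic (not merely span) overlap on the same
    strand.  Merged genes carry provisional ids; run
    :func:`assign_gene_identifiers` to adopt Ensembl ids and number novel
    genes.
    """
    report = MergeReport()
    txs: List[TranscriptModel] = []
    seen_ids = set()
    for annot, source in ((ensembl, "ensembl"), (isoseq, "isoseq")):
        for tx in annot.transcripts():
            if tx.source != source:
                tx = TranscriptModel(tx.transcript_id, tx.chain, source=source,
                                     gene_id=tx.gene_id,
                                     gene_name=tx.gene_name,
                                     support=tx.support, cds=tx.cds)
            if tx.transcript_id in seen_ids:
                raise ValidationError(
                    f"transcript id {tx.transcript_id!r} occurs in both "
                    f"annotations")
            seen_ids.add(tx.transcript_id)
            txs.append(tx)
    report.n_input_transcripts = len(txs)
    if dedup:
        txs = _dedup_transcripts(txs, report)
    txs.sort(key=lambda t: (t.chain.chrom, t.chain.start, t.chain.end,
                            t.transcript_id))
    report.n_output_transcripts = len(txs)

    # connected components over exonic overlap, same chrom+strand
    uf = _UnionFind(len(txs))
    trees: Dict[Tuple[str, str], IntervalTree] = {}
    for i, tx in enumerate(txs):
        key = (tx.chain.chrom, tx.chain.strand)
        tree = trees.setdefault(key, IntervalTree())
        for s, e in tx.chain.exons:
            for hit in tree.overlap(s, e):
                uf.union(i, hit.data)
            tree.addi(s, e, i)

    components: Dict[int, List[TranscriptModel]] = {}
    for i, tx in enumerate(txs):
        components.setdefault(uf.find(i), []).append(tx)

    genes: List[GeneModel] = []
    for k, members in sorted(components.items()):
        members.sort(key=lambda t: (t.chain.start, t.transcript_id))
        chrom = members[0].chain.chrom
        strand = members[0].chain.strand
        genes.append(GeneModel(f"MERGEG_{k:06d}", chrom, strand,
                               transcripts=members))
    merged = Annotation(genes)
    merged.validate()
    return merged, report


def assign_gene_identifiers(merged: Annotation, report: MergeReport
                            ) -> Annotation:
    """Adopt Ensembl gene ids/names; number isoseq-only genes.

    A merged gene containing transcripts from several distinct Ensembl
    genes adopts the id of the Ensembl gene contributing the most exonic
    overlap; the others are recorded in the report's conflict list.
    Novel (isoseq-only) genes get ``NOVELG_%06d`` ids in (chrom, start)
    order so numbering is deterministic.
    """
    ordered = sorted(merged.genes.values(),
                     key=lambda g: (g.chrom, g.start, g.gene_id))
    out: List[GeneModel] = []
    novel_counter = 0
    for gene in ordered:
        ens_txs = [t for t in gene.transcripts if t.source == "ensembl"
                   and t.gene_id]
        if not ens_txs:
            novel_counter += 1
            gid = NOVEL_GENE_FMT.format(novel_counter)
            out.append(GeneModel(gid, gene.chrom, gene.strand,
                                 transcripts=list(gene.transcripts)))
            continue
        gene_exons = merge_intervals(
            iv for t in gene.transcripts for iv in t.chain.exons)
        overlap_by_id: Dict[str, int] = {}
        name_by_id: Dict[str, Optional[str]] = {}
        for t in ens_txs:
            ov = intersect_len(gene_exons, t.chain.exons)
            overlap_by_id[t.gene_id] = overlap_by_id.get(t.gene_id, 0) + ov
            name_by_id.setdefault(t.gene_id, t.gene_name)
        adopted = max(sorted(overlap_by_id), key=lambda g: overlap_by_id[g])
        others = tuple(sorted(g for g in overlap_by_id if g != adopted))
        if others:
            report.id_conflicts.append((gene.gene_id, adopted, others))
        out.append(GeneModel(adopted, gene.chrom, gene.strand,
                             transcripts=list(gene.transcripts),
                             gene_name=name_by_id[adopted]))
    annot = Annotation(out)
    annot.validate()
    return annot


def merge_with_reference(ensembl: Annotation, isoseq: Annotation,
                         dedup: bool = True,
                         mito_chrom: Optional[str] = None
                         ) -> Tuple[Annotation, MergeReport]:
    """Convenience composition: merge, assign ids, optionally MT-prefix."""
    merged, report = merge_annotations(ensembl, isoseq, dedup=dedup)
    merged = assign_gene_identifiers(merged, report)
    if mito_chrom is not None:
        merged = apply_mito_prefix(merged, mito_chrom)
    return merged, report


def apply_mito_prefix(annot: Annotation, mito_chrom: str) -> Annotation:
    """Prefix gene names on the mitochondrial contig with ``MT-``.

    Genes whose name already starts with ``MT`` are left alone
    (idempotent); the base name falls back to the gene id when no name is
    set.  Raises when ``mito_chrom`` names no contig in the annotation.
    """
    if mito_chrom not in annot.chroms():
        raise ValueError(f"contig {mito_chrom!r} not present in annotation")
    out = []
    for gene in annot.genes.values():
        if gene.chrom == mito_chrom:
            base = gene.gene_name or gene.gene_id
            name = base if base.startswith("MT") else f"MT-{base}"
            out.append(GeneModel(gene.gene_id, gene.chrom, gene.strand,
                                 transcripts=list(gene.transcripts),
                                 gene_name=name))
        else:
            out.append(gene)
    return Annotation(out)
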