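"""Annotation-to-annotation comparison: strand-aware gene end shifts and
terminal-exon read counts.

The sign convention makes a 3'-UTR extension positive on either strand
and an earlier (more upstream) start negative on either strand:

* ``+`` strand: delta5 = new.start - old.start, delta3 = new.end - old.end
* ``-`` strand: delta5 = old.end - new.end,     delta3 = old.start - new.start

Only genes present in both annotations enter the medians; the lower
median is used for even n so summaries are deterministic integers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd

from .collapse import AlignedRead
from .core import Annotation, GeneModel


@dataclass
class EndShiftRecord:
    gene_id: str
    strand: str
    delta5: int
    delta3: int
    reads_first_exon_old: int = 0
    reads_first_exon_new: int = 0
    reads_last_exon_old: int = 0
    reads_last_exon_new: int = 0


@dataclass
class ComparisonSummary:
    median_delta5: float
    median_delta3: float
    median_first_exon_count_diff: float
    median_last_exon_count_diff: float
    n_genes: int


def lower_median(values: Sequence[float]) -> float:
    """Median with the lower of the two middle values for even n."""
    if not values:
        raise ValueError("median of empty sequence")
    ordered = sorted(values)
    return ordered[(len(ordered) - 1) // 2]


def gene_end_shifts(old: Annotation, new: Annotation,
                    counts_old: Optional[Dict[str, Tuple[int, int]]] = None,
                    counts_new: Optional[Dict[str, Tuple[int, int]]] = None
                    ) -> Tuple[List[EndShiftRecord], Dict[str, int]]:
    """Per-gene 5'/3' end shifts between two annotations.

    Genes are matched by gene id (run the merge id-assignment first when
    comparing against a merged annotation).  Genes present in only one
    annotation are excluded and counted in the returned report dict.
    Optional per-gene (first_exon, last_exon) read counts are attached.
    """
    shared = sorted(set(old.genes) & set(new.genes))
    report = {
        "shared": len(shared),
        "only_old": len(set(old.genes) - set(new.genes)),
        "only_new": len(set(new.genes) - set(old.genes)),
    }
    records: List[EndShiftRecord] = []
    for gid in shared:
        g_old, g_new = old.genes[gid], new.genes[gid]
        if g_old.strand != g_new.strand or g_old.chrom != g_new.chrom:
            report["strand_or_chrom_mismatch"] = \
                report.get("strand_or_chrom_mismatch", 0) + 1
            continue
        if g_old.strand == "+":
            delta5 = g_new.start - g_old.start
            delta3 = g_new.end - g_old.end
        else:
            delta5 = g_old.end - g_new.end
            delta3 = g_old.start - g_new.start
        co = counts_old.get(gid, (0, 0)) if counts_old else (0, 0)
        cn = counts_new.get(gid, (0, 0)) if counts_new else (0, 0)
        records.append(EndShiftRecord(
            gene_id=gid, strand=g_old.strand, delta5=delta5, delta3=delta3,
            reads_first_exon_old=co[0], reads_first_exon_new=cn[0],
            reads_last_exon_old=co[1], reads_last_exon_new=cn[1]))
    return records, report


def terminal_exon_read_counts(annot: Annotation,
                              alignments: Iterable[AlignedRead]
                              ) -> Dict[str, Tuple[int, int]]:
    """Per-gene (first exon, last exon) read counts.

    First/last exons are taken strand-aware from each gene's longest
    transcript.  A read counts toward an exon iff any of its aligned
    blocks overlaps that exon by >= 1 nt, at most once per exon.
    """
    targets: Dict[str, Tuple[GeneModel, Tuple[int, int], Tuple[int, int]]] = {}
    for gene in annot.genes.values():
        if not gene.transcripts:
            continue
        chain = gene.longest_transcript().chain
        if gene.strand == "+":
            first, last = chain.exons[0], chain.exons[-1]
        else:
            first, last = chain.exons[-1], chain.exons[0]
        targets[gene.gene_id] = (gene, first, last)

    counts = {gid: [0, 0] for gid in targets}
    for read in alignments:
        for gid, (gene, first, last) in targets.items():
            if read.chain.chrom != gene.chrom:
                continue
            blocks = read.chain.exons
            if any(min(e, first[1]) > max(s, first[0]) for s, e in blocks):
                counts[gid][0] += 1
            if any(min(e, last[1]) > max(s, last[0]) for s, e in blocks):
                counts[gid][1] += 1
    return {gid: (c[0], c[1]) for gid, c in counts.items()}


def summarize_shifts(records: Sequence[EndShiftRecord]) -> ComparisonSummary:
    if not records:
        raise ValueError("summarize_shifts requires at least one record")
    return ComparisonSummary(
        median_delta5=lower_median([r.delta5 for r in records]),
        median_delta3=lower_median([r.delta3 for r in records]),
        median_first_exon_count_diff=lower_median(
            [r.reads_first_exon_new - r.reads_first_exon_old
             for r in records]),
        median_last_exon_count_diff=lower_median(
            [r.reads_last_exon_new - r.reads_last_exon_old
             for r in records]),
        n_genes=len(records))


def records_to_table(records: Sequence[EndShiftRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])
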