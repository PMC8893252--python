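"""Primer/barcode resolution for barcoded full-length cDNA reads.

A sense-orientation read from a 10x 3' gene-expression construct (v3.1
NextGem chemistry) sequenced full-length looks like::

    [sample barcode] 5' primer | cDNA | polyA | rc(UMI) | rc(CB) | rc(3' primer) [rc(sample barcode)]

where CB is the 16 nt cell barcode and the UMI is 12 nt.  This module
locates the primers by semi-global edit distance, orients each read,
recovers the cell barcode, UMI and primer/polyA-free cDNA, classifies
reads by which structural elements are present, and removes PCR
duplicates by (cell barcode, UMI) key.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import edlib

from .core import revcomp

# 10x 3' GEX construct primers
DEFAULT_P5 = "CCCATGTACTCTGCGTTGATACCACTGCTT"
DEFAULT_P3 = "CTACACGACGCTCTTCCGATCT"
DEFAULT_SAMPLE_BARCODE = "ATATAGCGCGCGTGTG"

FULL_LENGTH = "FULL_LENGTH"
MISSING_5P = "MISSING_5P"
MISSING_3P = "MISSING_3P"
MISSING_BOTH = "MISSING_BOTH"
NO_POLYA = "NO_POLYA"
TOO_SHORT = "TOO_SHORT"

CATEGORIES = (FULL_LENGTH, MISSING_5P, MISSING_3P, MISSING_BOTH, NO_POLYA,
              TOO_SHORT)


@dataclass(frozen=True)
class ReadLayout:
    """Expected read structure and matching tolerances.

    ``cb_len``/``umi_len`` default to the published 10x 3' GEX v3.1
    lengths (16/12 nt); other chemistries are accommodated by overriding
    them.  ``umi_distal`` places the UMI farther from the 3' primer than
    the cell barcode, the 10x construct order; set False to swap.
    """

    p5_primer: str = DEFAULT_P5
    p3_primer: str = DEFAULT_P3
    sample_barcode: Optional[str] = DEFAULT_SAMPLE_BARCODE
    cb_len: int = 16
    umi_len: int = 12
    min_polya_len: int = 10
    max_non_a: int = 2
    max_primer_edits: int = 3
    max_barcode_edits: int = 2
    umi_distal: bool = True

    def __post_init__(self) -> None:
        for primer in (self.p5_primer, self.p3_primer):
            if not primer or set(primer) - set("ACGT"):
                raise ValueError(f"primer must be over ACGT, got {primer!r}")
        if self.cb_len <= 0 or self.umi_len <= 0:
            raise ValueError("cb_len and umi_len must be positive")


@dataclass(frozen=True)
class CcsRead:
    """A circular-consensus read."""

    read_id: str
    sequence: str
    mean_quality: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"read {self.read_id}: empty sequence")
        if set(self.sequence.upper()) - set("ACGTN"):
            raise ValueError(f"read {self.read_id}: non-ACGTN characters")


@dataclass
class ProcessedRead:
    """A read resolved into cell barcode, UMI and sense cDNA."""

    read_id: str
    category: str
    cell_barcode: str = ""
    umi: str = ""
    cdna: str = ""
    raw_orientation: str = "sense"
    polya_len: int = 0


@dataclass
class PrimerHit:
    start: int
    end: int  # half-open
    edits: int


def locate_primer(seq: str, primer: str, max_edits: int) -> Optional[PrimerHit]:
    """Best semi-global occurrence of ``primer`` in ``seq``.

    Returns the lowest-edit-distance hit; among equally good hits the
    leftmost is chosen.  ``None`` when the minimum edit distance exceeds
    ``max_edits``.
    """
    if len(primer) < 10:
        raise ValueError("primer must be >= 10 nt")
    res = edlib.align(primer, seq, mode="HW", task="locations", k=max_edits)
    if res["editDistance"] < 0:
        return None
    start, end = min(res["locations"])  # leftmost tie-break
    return PrimerHit(start=start, end=end + 1, edits=res["editDistance"])


def clip_sample_barcode(read: CcsRead, layout: ReadLayout) -> CcsRead:
    """Remove terminal sample-barcode occurrences (either end, either
    orientation); interior sequence is untouched."""
    bc = layout.sample_barcode
    if not bc:
        return read
    seq = read.sequence
    window = len(bc) + layout.max_barcode_edits + 4
    for probe in (bc, revcomp(bc)):
        # 5' end
        res = edlib.align(probe, seq[:window], mode="HW", task="locations",
                          k=layout.max_barcode_edits)
        if res["editDistance"] >= 0:
            _, end = min(res["locations"])
            seq = seq[end + 1:]
        # 3' end
        tail = seq[-window:] if len(seq) > window else seq
        offset = len(seq) - len(tail)
        res = edlib.align(probe, tail, mode="HW", task="locations",
                          k=layout.max_barcode_edits)
        if res["editDistance"] >= 0:
            start, end = max(res["locations"])
            if offset + end + 1 >= len(seq) - 2:  # terminal occurrence only
                seq = seq[:offset + start]
    if not seq:
        seq = "N"  # degenerate: read was all barcode
    return CcsRead(read.read_id, seq, read.mean_quality)


@dataclass
class OrientedRead:
    sequence: str
    p5_hit: Optional[PrimerHit]
    p3_hit: Optional[PrimerHit]  # hit of rc(p3_primer) near the 3' end
    raw_orientation: str
    category: str


def _find_structure(seq: str, layout: ReadLayout
                    ) -> Tuple[Optional[PrimerHit], Optional[PrimerHit]]:
    """Locate the 5' primer near the read start and rc(3' primer) near the
    read end.  Searches are confined to terminal windows (primers are
    ligated at the ends), which keeps chance interior matches from
    masquerading as construct structure."""
    slack = layout.max_primer_edits + 8 + \
        (len(layout.sample_barcode) if layout.sample_barcode else 0)
    w5 = len(layout.p5_primer) + slack
    p5 = locate_primer(seq[:w5], layout.p5_primer, layout.max_primer_edits)
    w3 = len(layout.p3_primer) + layout.cb_len + layout.umi_len + slack
    tail = seq[-w3:] if len(seq) > w3 else seq
    offset = len(seq) - len(tail)
    hit = locate_primer(tail, revcomp(layout.p3_primer),
                        layout.max_primer_edits)
    p3rc = PrimerHit(offset + hit.start, offset + hit.end, hit.edits) \
        if hit else None
    # guard for very short reads: the 5' primer must precede the 3' block
    if p5 and p3rc and p5.end > p3rc.start:
        if p5.start < len(seq) - p3rc.end:
            p3rc = None
        else:
            p5 = None
    return p5, p3rc


def orient_and_classify(read: CcsRead, layout: ReadLayout) -> OrientedRead:
    """Determine read orientation and which structural elements are present.

    Sense is defined as: the sequence begins with the 5' primer and ends
    with the reverse complement of the 3' primer.  When only the
    antisense pattern fits, the read is reverse-complemented and flagged
    ``antisense``.  A read matching fully in both orientations is a
    palindromic artifact and is rejected as MISSING_BOTH.
    """
    seq = read.sequence.upper()
    fwd5, fwd3 = _find_structure(seq, layout)
    rc_seq = revcomp(seq)
    rev5, rev3 = _find_structure(rc_seq, layout)

    fwd_full = fwd5 is not None and fwd3 is not None
    rev_full = rev5 is not None and rev3 is not None
    if fwd_full and rev_full:
        return OrientedRead(seq, None, None, "sense", MISSING_BOTH)
    if fwd_full:
        return OrientedRead(seq, fwd5, fwd3, "sense", FULL_LENGTH)
    if rev_full:
        return OrientedRead(rc_seq, rev5, rev3, "antisense", FULL_LENGTH)

    # partial structure: prefer the orientation with more evidence
    fwd_n = (fwd5 is not None) + (fwd3 is not None)
    rev_n = (rev5 is not None) + (rev3 is not None)
    if fwd_n == rev_n == 0:
        return OrientedRead(seq, None, None, "sense", MISSING_BOTH)
    if fwd_n >= rev_n:
        cat = MISSING_3P if fwd5 is not None else MISSING_5P
        return OrientedRead(seq, fwd5, fwd3, "sense", cat)
    cat = MISSING_3P if rev5 is not None else MISSING_5P
    return OrientedRead(rc_seq, rev5, rev3, "antisense", cat)


def trim_polya(seq: str, min_polya_len: int = 10,
               max_non_a: int = 2) -> Tuple[str, int]:
    """Remove a 3'-terminal polyA tail from a sense sequence.

    The tail is the maximal suffix that starts with an A and contains at
    most ``max_non_a`` non-A bases; it is removed only when its length is
    at least ``min_polya_len``.  Returns (trimmed sequence, tail length).
    """
    n = len(seq)
    non_a = 0
    best_start = None
    # walk from the 3' end, tracking the farthest qualifying suffix start
    for i in range(n - 1, -1, -1):
        if seq[i] != "A":
            non_a += 1
            if non_a > max_non_a:
                break
        else:
            best_start = i
    if best_start is None:
        return seq, 0
    tail_len = n - best_start
    if tail_len < min_polya_len:
        return seq, 0
    return seq[:best_start], tail_len


def extract_barcodes(oriented: OrientedRead, layout: ReadLayout
                     ) -> Optional[ProcessedRead]:
    """Recover cell barcode, UMI and cDNA from a structurally full read.

    On the sense strand the block immediately 5' of the rc(3' primer) is
    rc(cell barcode); the next block toward 5' is rc(UMI) (order
    swappable via ``layout.umi_distal``).  Returns ``None`` when the
    insert is too short to contain both blocks plus a polyA tail.
    """
    assert oriented.p5_hit is not None and oriented.p3_hit is not None
    seq = oriented.sequence
    insert = seq[oriented.p5_hit.end:oriented.p3_hit.start]
    bl = layout.cb_len + layout.umi_len
    if len(insert) < bl + layout.min_polya_len:
        return None
    if layout.umi_distal:
        cb = revcomp(insert[-layout.cb_len:])
        umi = revcomp(insert[-bl:-layout.cb_len])
    else:
        umi = revcomp(insert[-layout.umi_len:])
        cb = revcomp(insert[-bl:-layout.umi_len])
    body = insert[:-bl]
    cdna, tail = trim_polya(body, layout.min_polya_len, layout.max_non_a)
    if tail == 0:
        return ProcessedRead(read_id="", category=NO_POLYA, cell_barcode=cb,
                             umi=umi, cdna=body,
                             raw_orientation=oriented.raw_orientation)
    if not cdna:
        return None
    return ProcessedRead(read_id="", category=FULL_LENGTH, cell_barcode=cb,
                         umi=umi, cdna=cdna,
                         raw_orientation=oriented.raw_orientation,
                         polya_len=tail)


def deduplicate_reads(reads: Iterable[ProcessedRead]
                      ) -> Tuple[List[ProcessedRead], int]:
    """One representative per (cell barcode, UMI): the longest cDNA, ties
    broken by lexicographically smallest read id.  Returns (unique reads,
    number of duplicates removed)."""
    groups: Dict[Tuple[str, str], ProcessedRead] = {}
    n_dup = 0
    for read in reads:
        key = (read.cell_barcode, read.umi)
        cur = groups.get(key)
        if cur is None:
            groups[key] = read
        else:
            n_dup += 1
            # longer cdna wins; equal length -> smaller read_id wins
            if len(read.cdna) > len(cur.cdna) or (
                    len(read.cdna) == len(cur.cdna)
                    and read.read_id < cur.read_id):
                groups[key] = read
    unique = sorted(groups.values(), key=lambda r: r.read_id)
    return unique, n_dup


@dataclass
class ProcessingResult:
    full_length: List[ProcessedRead]
    rejects: List[ProcessedRead]
    counts: Counter
    n_duplicates: int

    @property
    def n_input(self) -> int:
        return sum(self.counts.values())


def process_reads(reads: Iterable[CcsRead], layout: ReadLayout,
                  deduplicate: bool = True) -> ProcessingResult:
    """Full read-resolution pipeline: sample-barcode clipping, primer
    orientation, barcode/UMI extraction, polyA trimming, duplicate
    filtering.

    Every input read lands in exactly one category; ``counts`` sums to
    the number of inputs.  Rejected reads (anything not FULL_LENGTH) are
    returned separately for writing to their own file.
    """
    accepted: List[ProcessedRead] = []
    rejects: List[ProcessedRead] = []
    counts: Counter = Counter()
    for read in reads:
        clipped = clip_sample_barcode(read, layout)
        oriented = orient_and_classify(clipped, layout)
        if oriented.category != FULL_LENGTH:
            counts[oriented.category] += 1
            rejects.append(ProcessedRead(read_id=read.read_id,
                                         category=oriented.category,
                                         raw_orientation=oriented.raw_orientation))
            continue
        result = extract_barcodes(oriented, layout)
        if result is None:
            counts[TOO_SHORT] += 1
            rejects.append(ProcessedRead(read_id=read.read_id,
                                         category=TOO_SHORT,
                                         raw_orientation=oriented.raw_orientation))
            continue
        result.read_id = read.read_id
        counts[result.category] += 1
        if result.category == FULL_LENGTH:
            accepted.append(result)
        else:
            rejects.append(result)
    n_dup = 0
    if deduplicate:
        accepted, n_dup = deduplicate_reads(accepted)
    return ProcessingResult(full_length=accepted, rejects=rejects,
                            counts=counts, n_duplicates=n_dup)


def write_processed_fasta(reads: Sequence[ProcessedRead], path) -> None:
    """FULL_LENGTH reads as FASTA with cb/umi in key=value header tags."""
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f">{r.read_id} cb={r.cell_barcode} umi={r.umi} "
                     f"polya={r.polya_len}\n{r.cdna}\n")


def write_rejects_fasta(reads: Sequence[ProcessedRead],
                        originals: Dict[str, str], path) -> None:
    """Non-conforming reads, raw sequence, category in the header."""
    with open(path, "w") as fh:
        for r in reads:
            seq = originals.get(r.read_id, "")
            fh.write(f">{r.read_id} category={r.category}\n{seq}\n")
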