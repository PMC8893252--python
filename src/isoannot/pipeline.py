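"""End-to-end pipeline driver and run configuration.

Stages: process reads -> (external splice-aware alignment, or a simulated
SAM) -> coverage/identity filter + collapse -> classify/filter ->
merge with the reference -> end-shift comparison.  Each stage writes its
artifacts plus a JSON summary into the run directory; reruns with
identical inputs and config are byte-identical.

Alignment itself is an explicit external step: the recommended
splice-aware aligner invocation is printed as guidance
(``minimap2 -ax splice -uf ref.fa reads.fa``) but never shelled out to,
so runs do not depend on an aligner being installed or pinned.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Any, Dict, List, Optional

import yaml

from . import classify as cls
from . import compare as cmp_mod
from . import io_formats as iof
from . import merge as merge_mod
from .collapse import collapse_isoforms, filter_alignments
from .read_processing import (
    CcsRead,
    ReadLayout,
    process_reads,
    write_processed_fasta,
    write_rejects_fasta,
)

MINIMAP2_HINT = ("external alignment step, e.g.: "
                 "minimap2 -ax splice -uf <genome.fa> <processed.fa>")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and cause."""

    def __init__(self, stage: str, cause: str) -> None:
        super().__init__(f"stage={stage}: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """All tunables of the pipeline in one flat, serialisable record."""

    # read layout
    p5_primer: str = ReadLayout.p5_primer
    p3_primer: str = ReadLayout.p3_primer
    sample_barcode: Optional[str] = ReadLayout.sample_barcode
    cb_len: int = 16
    umi_len: int = 12
    min_polya_len: int = 10
    max_non_a: int = 2
    max_primer_edits: int = 3
    max_barcode_edits: int = 2
    # collapse
    c_min: float = 0.99
    i_min: float = 0.95
    junction_tol: int = 0
    mono_exon_min_overlap: float = 0.5
    # classification / artifact filters
    end_tol: int = 50
    ip_window: int = 20
    ip_a_frac: float = 0.6
    rt_repeat_len: int = 8
    exempt_fsm_from_intra_priming: bool = True
    # merge
    dedup: bool = True
    mito_chrom: Optional[str] = None
    # inputs
    reads_fasta: Optional[str] = None
    alignments_sam: Optional[str] = None
    reference_gtf: Optional[str] = None
    genome_fasta: Optional[str] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.c_min <= 1 or not 0 < self.i_min <= 1:
            raise ValueError("c_min and i_min must lie in (0, 1]")
        if self.junction_tol < 0 or self.end_tol < 0:
            raise ValueError("tolerances must be non-negative")
        if not 0 < self.ip_a_frac <= 1:
            raise ValueError("ip_a_frac must lie in (0, 1]")
        if self.rt_repeat_len < 4:
            raise ValueError("rt_repeat_len must be >= 4")

    def layout(self) -> ReadLayout:
        return ReadLayout(
            p5_primer=self.p5_primer, p3_primer=self.p3_primer,
            sample_barcode=self.sample_barcode, cb_len=self.cb_len,
            umi_len=self.umi_len, min_polya_len=self.min_polya_len,
            max_non_a=self.max_non_a, max_primer_edits=self.max_primer_edits,
            max_barcode_edits=self.max_barcode_edits)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def validate_summary(summary: Dict[str, Any]) -> None:
    """Check a stage summary against the bundled schema contract."""
    if "stage" not in summary or not isinstance(summary["stage"], str):
        raise ValueError("summary missing string 'stage'")
    counts = summary.get("counts")
    if not isinstance(counts, dict):
        raise ValueError("summary missing 'counts' mapping")
    for key, value in counts.items():
        if not isinstance(value, int) or value < 0:
            raise ValueError(f"count {key!r} must be a non-negative integer")


def _write_summary(run_dir: Path, stage: str, payload: Dict[str, Any]) -> None:
    payload = {"stage": stage, **payload}
    validate_summary(payload)
    with open(run_dir / f"{stage}.summary.json", "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _read_ccs_fasta(path: str) -> List[CcsRead]:
    from Bio import SeqIO

    return [CcsRead(rec.id, str(rec.seq).upper())
            for rec in SeqIO.parse(path, "fasta")]


def run_pipeline(config: PipelineConfig, run_dir) -> Dict[str, Any]:
    """Execute all stages for which inputs are configured.

    Returns a manifest dict (also written to ``manifest.json``).  A stage
    failure raises :class:`PipelineError` naming the stage; artifacts of
    completed stages are retained.
    """
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    manifest: Dict[str, Any] = {"stages": []}
    config.to_yaml(run_dir / "config.yaml")

    # --- process ---------------------------------------------------------
    if config.reads_fasta:
        try:
            reads = _read_ccs_fasta(config.reads_fasta)
            result = process_reads(reads, config.layout())
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("process", str(exc)) from exc
        write_processed_fasta(result.full_length, run_dir / "processed.fasta")
        originals = {r.read_id: r.sequence for r in reads}
        write_rejects_fasta(result.rejects, originals,
                            run_dir / "rejects.fasta")
        _write_summary(run_dir, "process", {
            "counts": dict(sorted(result.counts.items())),
            "n_duplicates_removed": result.n_duplicates,
            "n_full_length_unique": len(result.full_length),
            "alignment_hint": MINIMAP2_HINT,
        })
        manifest["stages"].append("process")

    # --- collapse --------------------------------------------------------
    transcripts = None
    if config.alignments_sam:
        try:
            aligned, skipped = iof.parse_sam_alignments(config.alignments_sam)
            passing, rejected = filter_alignments(aligned, config.c_min,
                                                  config.i_min)
            transcripts = collapse_isoforms(
                passing, junction_tol=config.junction_tol,
                mono_exon_min_overlap=config.mono_exon_min_overlap)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("collapse", str(exc)) from exc
        collapsed = _transcripts_to_annotation(transcripts)
        iof.write_gtf(collapsed, run_dir / "collapsed.gtf")
        with open(run_dir / "collapsed.support.tsv", "w") as fh:
            fh.write("transcript_id\tn_reads\tread_ids\n")
            for tx in transcripts:
                fh.write(f"{tx.transcript_id}\t{len(tx.support)}\t"
                         f"{','.join(tx.support)}\n")
        _write_summary(run_dir, "collapse", {
            "counts": {"aligned": len(aligned), "passing": len(passing),
                       "filtered_out": rejected,
                       "transcripts": len(transcripts), **skipped},
        })
        manifest["stages"].append("collapse")

    # --- classify / artifact filter -------------------------------------
    retained_txs = transcripts
    if transcripts is not None and config.reference_gtf:
        try:
            ref = iof.read_gtf(config.reference_gtf)
            calls = {t.transcript_id: cls.classify_isoform(t, ref,
                                                           config.end_tol)
                     for t in transcripts}
            genome = iof.read_fasta(config.genome_fasta) \
                if config.genome_fasta else None
            if genome is not None:
                flags = {t.transcript_id: cls.compute_filter_flags(
                    t, genome, config.ip_window, config.ip_a_frac,
                    config.rt_repeat_len) for t in transcripts}
            else:
                flags = {t.transcript_id: cls.FilterFlags(t.transcript_id)
                         for t in transcripts}
            report = cls.filter_isoforms(
                transcripts, calls, flags,
                exempt_fsm_from_intra_priming=
                config.exempt_fsm_from_intra_priming)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("classify", str(exc)) from exc
        retained_txs = report.retained
        table = cls.calls_to_table([calls[t.transcript_id]
                                    for t in transcripts], flags)
        table.to_csv(run_dir / "classification.tsv", sep="\t", index=False)
        cls.classification_summary(list(calls.values())).to_csv(
            run_dir / "classification.summary.tsv", sep="\t", index=False)
        iof.write_gtf(_transcripts_to_annotation(report.retained),
                      run_dir / "filtered.gtf")
        _write_summary(run_dir, "classify", {
            "counts": {"classified": len(calls),
                       "retained": len(report.retained),
                       "removed": len(report.removed),
                       "fsm_exempted": report.fsm_exempted},
        })
        manifest["stages"].append("classify")

    # --- merge -----------------------------------------------------------
    merged = None
    if retained_txs is not None and config.reference_gtf:
        try:
            ref = iof.read_gtf(config.reference_gtf)
            iso_annot = _transcripts_to_annotation(retained_txs)
            merged, mreport = merge_mod.merge_with_reference(
                ref, iso_annot, dedup=config.dedup,
                mito_chrom=config.mito_chrom)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("merge", str(exc)) from exc
        iof.write_gtf(merged, run_dir / "merged.gtf")
        _write_summary(run_dir, "merge", {
            "counts": {
                "input_transcripts": mreport.n_input_transcripts,
                "output_transcripts": mreport.n_output_transcripts,
                "duplicates_removed": len(mreport.duplicates_removed),
                "id_conflicts": len(mreport.id_conflicts),
                "genes": len(merged),
            },
        })
        manifest["stages"].append("merge")

    # --- compare ---------------------------------------------------------
    if merged is not None and config.reference_gtf:
        try:
            ref = iof.read_gtf(config.reference_gtf)
            records, report_cmp = cmp_mod.gene_end_shifts(ref, merged)
            summary = cmp_mod.summarize_shifts(records) if records else None
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("compare", str(exc)) from exc
        cmp_mod.records_to_table(records).to_csv(
            run_dir / "end_shifts.tsv", sep="\t", index=False)
        payload: Dict[str, Any] = {"counts": {k: v for k, v in
                                              report_cmp.items()}}
        if summary:
            payload.update({
                "median_delta5": float(summary.median_delta5),
                "median_delta3": float(summary.median_delta3),
            })
        _write_summary(run_dir, "compare", payload)
        manifest["stages"].append("compare")

    with open(run_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def _transcripts_to_annotation(transcripts) -> "iof.Annotation":
    """Wrap loose transcript models into per-locus single-transcript genes
    keyed by the PB locus (PB.<locus>.<n> -> gene PB.<locus>)."""
    from .core import Annotation, GeneModel

    genes: Dict[str, GeneModel] = {}
    for tx in transcripts:
        if tx.transcript_id.startswith("PB.") and \
                tx.transcript_id.count(".") == 2:
            gid = tx.gene_id or ".".join(tx.transcript_id.split(".")[:2])
        else:
            gid = tx.gene_id or f"{tx.transcript_id}_G"
        if gid not in genes:
            genes[gid] = GeneModel(gid, tx.chrom, tx.strand)
        genes[gid].transcripts.append(tx)
    annot = Annotation(genes.values())
    annot.validate()
    return annot
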