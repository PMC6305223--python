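"""End-to-end orchestration: align contigs, build the windowed MSA, emit
both VCFs, and write a run report with summary statistics."""

from __future__ import annotations

import json
import logging
from concurrent.futures import ProcessPoolExecutor
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import chaining, graph, windows
from .io import (
    GappedAlignmentRecord,
    SequenceRecord,
    gapped_rows_to_records,
    read_fasta,
    ungapped,
    write_pairwise_sam,
    write_vcf,
)

logger = logging.getLogger("novograph")


@dataclass
class PipelineConfig:
    """Resolved run configuration; written next to the outputs for
    reproducibility."""

    reference: str
    contigs: str
    outdir: str
    engine: str = "internal"  # local aligner: internal | bwa | minimap2
    msa_engine: str = "internal"  # internal | mafft
    window_size: int = 10_000
    boundary_scan: int = 100
    gap_score: int = -1
    seed_k: int = 15
    u1: int = 5000
    u2: int = 5000
    seed: int = 0
    n_workers: int = 1

    def __post_init__(self):
        for name in ("window_size", "boundary_scan", "seed_k", "u1", "u2", "n_workers"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.window_size <= 2 * self.boundary_scan:
            raise ValueError("window_size must exceed twice the boundary scan radius")
        if self.gap_score >= 0:
            raise ValueError("gap_score must be negative")


@dataclass
class PipelineResult:
    report: dict
    alignments: list = field(default_factory=list)
    msas: dict = field(default_factory=dict)
    simple_records: list = field(default_factory=list)
    universal_records: list = field(default_factory=list)


def _align_one_window(args):
    ws, engine = args
    return windows.align_window(ws, engine=engine)


def align_contigs(
    contigs: list[SequenceRecord],
    reference: list[SequenceRecord],
    engine: str = "internal",
    seed_k: int = 15,
    gap_score: int = -1,
) -> tuple[list[chaining.GlobalAlignment], list[str]]:
    """Step 1 over all contigs; returns (alignments, unaligned contig ids)."""
    aligned, unaligned = [], []
    for contig in contigs:
        aln = chaining.global_align_contig(
            contig, reference, engine=engine, k=seed_k, gap_score=gap_score
        )
        if aln is None:
            unaligned.append(contig.id)
        else:
            aligned.append(aln)
    return aligned, unaligned


def build_msas(
    alignments: list[chaining.GlobalAlignment],
    reference: list[SequenceRecord],
    msa_engine: str = "internal",
    window_size: int = 10_000,
    boundary_scan: int = 100,
    n_workers: int = 1,
) -> tuple[dict[str, windows.ConcatenatedMsa], dict[str, list[windows.Window]]]:
    """Step 2 per reference contig. Window MSAs are independent, so worker
    count affects scheduling only, never the result."""
    msas: dict[str, windows.ConcatenatedMsa] = {}
    window_table: dict[str, list[windows.Window]] = {}
    for ref in reference:
        alns = [a for a in alignments if a.ref_id == ref.id]
        wins = windows.choose_window_boundaries(
            alns, ref, window_size=window_size, boundary_scan=boundary_scan
        )
        window_table[ref.id] = wins
        sets = windows.build_window_sets(alns, wins, ref)
        jobs = [(ws, msa_engine) for ws in sets]
        if n_workers > 1 and len(jobs) > 1:
            with ProcessPoolExecutor(max_workers=n_workers) as pool:
                per_window = list(pool.map(_align_one_window, jobs, chunksize=4))
        else:
            per_window = [_align_one_window(j) for j in jobs]
        msas[ref.id] = windows.concatenate_windows(per_window)
    return msas, window_table


def compute_divergence(alignments: list[chaining.GlobalAlignment]) -> pd.DataFrame:
    """Per-contig NM/length divergence table.

    NM is the exact Levenshtein distance between the aligned (oriented)
    contig and the reference slice it covers — the chained alignment itself
    can render two nearby substitutions as a larger paired gap, which would
    overstate the mismatch+inserted+deleted count. Length is the aligned
    contig length."""
    import edlib

    rows = []
    for aln in alignments:
        contig_seq = ungapped(aln.aligned_contig)
        ref_slice = ungapped(aln.aligned_ref)
        nm = edlib.align(contig_seq, ref_slice, mode="NW", task="distance")["editDistance"]
        length = len(contig_seq)
        rows.append(
            {
                "contig_id": aln.contig_id,
                "NM": nm,
                "length": length,
                "divergence": nm / length if length else float("nan"),
            }
        )
    return pd.DataFrame(rows, columns=["contig_id", "NM", "length", "divergence"])


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run Steps 1-3 and write all artifacts into ``config.outdir``.

    Artifacts: step1.sam, windows.bed, msa.sam, simple.vcf, universal.vcf,
    divergence.tsv, dropped_contigs.tsv, report.json, config.json.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "config.json", "w") as fh:
        json.dump(asdict(config), fh, indent=2, sort_keys=True)

    reference = read_fasta(config.reference)
    contigs = read_fasta(config.contigs)

    # Step 1
    alignments, unaligned = align_contigs(
        contigs, reference, engine=config.engine, seed_k=config.seed_k,
        gap_score=config.gap_score,
    )
    for cid in unaligned:
        logger.warning("contig %s failed to generate initial alignments", cid)
    write_pairwise_sam([a.to_record() for a in alignments], reference, outdir / "step1.sam")
    compute_divergence(alignments).to_csv(outdir / "divergence.tsv", sep="\t", index=False)

    # Step 2
    msas, window_table = build_msas(
        alignments, reference, msa_engine=config.msa_engine,
        window_size=config.window_size, boundary_scan=config.boundary_scan,
        n_workers=config.n_workers,
    )
    with open(outdir / "windows.bed", "w") as fh:
        for ref in reference:
            for w in window_table[ref.id]:
                fh.write(f"{w.ref_id}\t{w.start}\t{w.end}\n")
    msa_records: list[GappedAlignmentRecord] = []
    for ref in reference:
        msa = msas[ref.id]
        msa_records.extend(gapped_rows_to_records(ref.id, msa.ref_row, msa.rows))
    _write_msa_multi(msa_records, reference, outdir / "msa.sam")

    # Step 3
    limits = graph.GraphLimits(u1=config.u1, u2=config.u2)
    simple_records, universal_records, dropped = [], [], []
    for ref in reference:
        simple_records.extend(graph.build_simple_vcf(msas[ref.id]))
        recs, drop = graph.universal_build(msas[ref.id], limits)
        universal_records.extend(recs)
        dropped.extend(drop)
    write_vcf(simple_records, reference, outdir / "simple.vcf")
    write_vcf(universal_records, reference, outdir / "universal.vcf")
    with open(outdir / "dropped_contigs.tsv", "w") as fh:
        fh.write("contig_id\treason\tcolumn\n")
        for d in dropped:
            fh.write(f"{d.contig_id}\t{d.reason}\t{d.column}\n")

    def vcf_stats(records):
        return {
            "sites": len(records),
            "alleles": sum(len(r.alt_alleles) for r in records),
        }

    report = {
        "contigs_in": len(contigs),
        "contigs_aligned": len(alignments),
        "contigs_unaligned": len(unaligned),
        "unaligned_ids": sorted(unaligned),
        "contigs_dropped_u1": len({d.contig_id for d in dropped}),
        "simple": vcf_stats(simple_records),
        "universal": vcf_stats(universal_records),
        "windows": {r.id: len(window_table[r.id]) for r in reference},
    }
    assert report["contigs_in"] == report["contigs_aligned"] + report["contigs_unaligned"]
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return PipelineResult(
        report=report,
        alignments=alignments,
        msas=msas,
        simple_records=simple_records,
        universal_records=universal_records,
    )


def _write_msa_multi(records, refs, path):
    # write_msa_sam validates against a single reference; the pipeline's
    # combined file spans all of them, so validate per record here.
    import pysam

    from .io import _sam_header  # shared header construction

    header = _sam_header(refs)
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for rec in sorted(records, key=lambda r: (header.get_tid(r.ref_id), r.pos, r.query_id)):
            seg = pysam.AlignedSegment(header)
            seg.query_name = rec.query_id
            seg.reference_id = header.get_tid(rec.ref_id)
            seg.reference_start = rec.pos - 1
            seg.mapping_quality = 60
            seg.cigarstring = rec.cigar
            seg.query_sequence = rec.sequence
            out.write(seg)
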